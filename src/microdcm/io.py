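"""Tables, structured result containers, and cohort persistence.

Human-facing tables are strict CSV (comma separated, header row, UTF-8,
'.' decimal, full float precision).  Structured results (fits, cohorts,
pipeline outputs) use HDF5: hierarchical arrays plus attributes carrying the
package version, seeds and a configuration hash for provenance.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .cmc import ModelError
from .forward import CrossSpectrum, ErpTimeSeries
from .inversion import FitResult, Posterior


class TableError(ValueError):
    pass


def write_table(path, table):
    """Write a DataFrame (or dict of columns) as strict CSV, full precision."""
    df = pd.DataFrame(table)
    df.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")


def read_table(path):
    """Read a strict-dialect CSV; malformed rows raise with their index."""
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise TableError(f"{path}: empty table")
    header = rows[0]
    ncol = len(header)
    data = {h: [] for h in header}
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != ncol:
            raise TableError(f"{path}: ragged row at line {i} "
                             f"({len(row)} fields, expected {ncol})")
        for h, cell in zip(header, row):
            data[h].append(cell)
    df = pd.DataFrame(data)
    for col in df.columns:
        s = df[col]
        if s.str.contains(",").any():
            raise TableError(
                f"{path}: column {col!r} contains ',' inside a field -- "
                "decimal commas are not accepted (use '.')")
        try:
            df[col] = pd.to_numeric(s)
        except (ValueError, TypeError):
            pass
    return df


def config_hash(config):
    """Stable hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# -- HDF5 containers ---------------------------------------------------------


def _write_node(grp, key, value):
    if isinstance(value, dict):
        sub = grp.create_group(key)
        sub.attrs["_type"] = "dict"
        for k, v in value.items():
            _write_node(sub, str(k), v)
    elif isinstance(value, (list, tuple)) and value and isinstance(
            value[0], str):
        grp.create_dataset(key, data=np.array(value, dtype="S"))
        grp[key].attrs["_type"] = "strlist"
    elif isinstance(value, str):
        grp.attrs[key] = value
    elif isinstance(value, (bool, np.bool_)):
        grp.attrs[key] = bool(value)
    elif np.isscalar(value):
        grp.attrs[key] = value
    elif value is None:
        grp.attrs[key] = "__none__"
    else:
        grp.create_dataset(key, data=np.asarray(value))


def _read_node(grp):
    out = {}
    for k, v in grp.attrs.items():
        if k == "_type":
            continue
        out[k] = None if (isinstance(v, str) and v == "__none__") else v
    for k, item in grp.items():
        if isinstance(item, h5py.Group):
            out[k] = _read_node(item)
        elif item.attrs.get("_type") == "strlist":
            out[k] = [s.decode() for s in item[()]]
        else:
            out[k] = item[()]
    return out


def save_results(path, data, config=None, seed=None):
    """Write a nested dict of arrays/scalars/strings to an HDF5 container."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as fh:
        fh.attrs["microdcm_version"] = __version__
        if seed is not None:
            fh.attrs["seed"] = int(seed)
        if config is not None:
            fh.attrs["config_hash"] = config_hash(config)
            fh.attrs["config_json"] = json.dumps(config, sort_keys=True,
                                                 default=str)
        for k, v in data.items():
            _write_node(fh, k, v)


def load_results(path):
    with h5py.File(path, "r") as fh:
        return _read_node(fh)


# -- domain-object (de)serialization ----------------------------------------


def csd_to_dict(csd: CrossSpectrum):
    return dict(kind="csd", grid=csd.grid, real=csd.values.real,
                imag=csd.values.imag,
                condition=csd.condition or "")


def erp_to_dict(erp: ErpTimeSeries):
    d = dict(kind="erp", t_ms=erp.t_ms, onset_ms=erp.onset_ms,
             conditions=sorted(erp.traces))
    for cond in erp.traces:
        d[f"trace_{cond}"] = np.asarray(erp.traces[cond])
    return d


def dict_to_data(d):
    if d["kind"] == "csd":
        return CrossSpectrum(d["grid"], d["real"] + 1j * d["imag"],
                             condition=d.get("condition") or None)
    if d["kind"] == "erp":
        traces = {c: d[f"trace_{c}"] for c in d["conditions"]}
        return ErpTimeSeries(d["t_ms"], traces, onset_ms=float(d["onset_ms"]))
    raise ModelError(f"unknown payload kind {d.get('kind')!r}")


def posterior_to_dict(post: Posterior):
    return dict(names=list(post.names), mean=post.mean, cov=post.cov,
                prior_mean=post.prior_mean, prior_cov=post.prior_cov,
                hyper_mean=post.hyper_mean, hyper_cov=post.hyper_cov,
                free_energy=post.free_energy, trace=np.asarray(post.trace),
                converged=post.converged)


def dict_to_posterior(d):
    return Posterior(names=list(d["names"]), mean=d["mean"], cov=d["cov"],
                     prior_mean=d["prior_mean"], prior_cov=d["prior_cov"],
                     hyper_mean=d["hyper_mean"], hyper_cov=d["hyper_cov"],
                     free_energy=float(d["free_energy"]),
                     trace=list(d["trace"]), converged=bool(d["converged"]))


def save_fit(path, fit: FitResult, config=None, seed=None):
    save_results(path, dict(posterior=posterior_to_dict(fit.posterior),
                            prediction=fit.prediction, r2=fit.r2),
                 config=config, seed=seed)


def load_fit(path):
    d = load_results(path)
    return FitResult(dict_to_posterior(d["posterior"]), d["prediction"],
                     float(d["r2"]))


def save_cohort(directory, subjects, spec=None):
    """One HDF5 file per subject plus a JSON manifest with spec and seeds."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = dict(version=__version__, n_subjects=len(subjects),
                    subjects=[], spec=None)
    if spec is not None:
        manifest["spec"] = {k: v for k, v in vars(spec).items()
                            if isinstance(v, (int, float, str, bool, tuple,
                                              list, dict))}
    for sub in subjects:
        fname = f"{sub.subject_id}.h5"
        payload = dict(group=sub.group, seed=sub.seed,
                       covariates=sub.covariates, symptoms=sub.symptoms,
                       true_params={p: dict(v) for p, v in
                                    sub.true_params.items()},
                       data={p: (csd_to_dict(d) if isinstance(d, CrossSpectrum)
                                 else erp_to_dict(d))
                             for p, d in sub.data.items()})
        save_results(directory / fname, payload, seed=sub.seed)
        manifest["subjects"].append(dict(id=sub.subject_id, group=sub.group,
                                         seed=sub.seed, file=fname))
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def load_cohort(directory):
    from .cohort import SubjectRecord

    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    subjects = []
    for entry in manifest["subjects"]:
        d = load_results(directory / entry["file"])
        subjects.append(SubjectRecord(
            subject_id=entry["id"], group=d["group"], seed=int(d["seed"]),
            covariates=d["covariates"], symptoms=d["symptoms"],
            true_params={p: {k: float(v) for k, v in th.items()}
                         for p, th in d["true_params"].items()},
            data={p: dict_to_data(payload)
                  for p, payload in d["data"].items()}))
    return subjects
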