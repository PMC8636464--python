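"""Long-format CSV data interchange, unit rescaling and run manifests.

The on-disk format is one row per (person, item) cell:
``person_id,item_id,rt,accuracy`` with strictly positive response times in
the caller's time unit and accuracy in {0, 1}.  Fitting requires a complete
persons x items cross; validation reports every malformed cell by id.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .simulate import EffectSet, ResponseMatrix

__all__ = [
    "ValidationError",
    "read_long_csv",
    "write_long_csv",
    "to_long_frame",
    "read_covariates",
    "rescale_units",
    "RunManifest",
]

REQUIRED_COLUMNS = ("person_id", "item_id", "rt", "accuracy")


class ValidationError(ValueError):
    """Input data failed validation; ``problems`` itemises every violation."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("input validation failed:\n  " + "\n  ".join(problems))


def to_long_frame(mat: ResponseMatrix, item_ids=None, person_ids=None) -> pd.DataFrame:
    """Flatten a response matrix to the long format (row-major over items)."""
    items = (np.asarray(item_ids) if item_ids is not None
             else np.array([f"i{k:03d}" for k in range(mat.n_items)]))
    persons = (np.asarray(person_ids) if person_ids is not None
               else np.array([f"p{k:03d}" for k in range(mat.n_persons)]))
    ii, pp = np.meshgrid(np.arange(mat.n_items), np.arange(mat.n_persons),
                         indexing="ij")
    return pd.DataFrame({
        "person_id": persons[pp.ravel()],
        "item_id": items[ii.ravel()],
        "rt": mat.t.ravel(),
        "accuracy": mat.x.ravel(),
    })


def write_long_csv(path, mat: ResponseMatrix, item_ids=None, person_ids=None) -> None:
    # %.17g guarantees a bit-exact float round trip through the text format
    to_long_frame(mat, item_ids, person_ids).to_csv(
        path, index=False, float_format="%.17g")


def read_long_csv(path):
    """Load a long-format CSV and pivot to matrices.

    Returns ``(ResponseMatrix, item_ids, person_ids)``.  Ids are ordered by
    first appearance in the file (stable, documented ordering).  Duplicated
    (person, item) pairs, missing cells, non-positive RTs and accuracies
    outside {0, 1} raise a :class:`ValidationError` listing every problem.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    problems = []
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError([f"missing required column(s): {missing_cols}"])

    dup = df.duplicated(subset=["person_id", "item_id"], keep=False)
    for _, row in df[dup].drop_duplicates(["person_id", "item_id"]).iterrows():
        problems.append(f"duplicate cell person_id={row.person_id!r} "
                        f"item_id={row.item_id!r}")
    bad_rt = ~(pd.to_numeric(df["rt"], errors="coerce") > 0)
    for _, row in df[bad_rt].iterrows():
        problems.append(f"non-positive rt={row.rt!r} at person_id="
                        f"{row.person_id!r} item_id={row.item_id!r}")
    bad_x = ~df["accuracy"].isin([0, 1])
    for _, row in df[bad_x].iterrows():
        problems.append(f"accuracy {row.accuracy!r} not in {{0,1}} at "
                        f"person_id={row.person_id!r} item_id={row.item_id!r}")

    item_ids = df["item_id"].drop_duplicates().to_numpy()
    person_ids = df["person_id"].drop_duplicates().to_numpy()
    have = set(zip(df["person_id"], df["item_id"]))
    for i in item_ids:
        for p in person_ids:
            if (p, i) not in have:
                problems.append(f"missing cell person_id={p!r} item_id={i!r}")
    if problems:
        raise ValidationError(problems)

    pivot_t = df.pivot(index="item_id", columns="person_id", values="rt")
    pivot_x = df.pivot(index="item_id", columns="person_id", values="accuracy")
    pivot_t = pivot_t.loc[item_ids, person_ids]
    pivot_x = pivot_x.loc[item_ids, person_ids]
    mat = ResponseMatrix(t=pivot_t.to_numpy(float), x=pivot_x.to_numpy(int))
    return mat, item_ids, person_ids


def read_covariates(path, person_ids) -> np.ndarray:
    """Person-level covariates aligned to ``person_ids`` order."""
    df = pd.read_csv(path)
    if "person_id" not in df.columns:
        raise ValidationError(["covariate file lacks a person_id column"])
    df = df.set_index("person_id")
    missing = [p for p in person_ids if p not in df.index]
    if missing:
        raise ValidationError([f"no covariates for person_id={p!r}" for p in missing])
    return df.loc[list(person_ids)].to_numpy(float)


def rescale_units(mat: ResponseMatrix, factor: float) -> ResponseMatrix:
    """Multiply all response times by ``factor`` (e.g. 10 for tenths -> ...).

    The ABDM density depends on the effects only through ``(beta+theta) *
    alpha~`` and on ``c``; rescaling ``t -> k t`` maps a fitted model back to
    the original units via ``alpha~ -> alpha~ / sqrt(k)``, ``c -> c /
    sqrt(k)`` with ``beta``/``theta`` untouched, and shifts every cell's log
    density by ``-log k`` (the Jacobian).  Fits in rescaled units are
    therefore equivalent; report effects in the input scale using this map.
    """
    if not factor > 0:
        raise ValueError("factor must be > 0")
    return ResponseMatrix(t=mat.t * factor, x=mat.x.copy())


def rescale_fit(effects: EffectSet, c: float, factor: float):
    """Map (effects, c) fitted on ``t * factor`` back to the ``t`` scale."""
    k = float(factor)
    return (EffectSet(beta=effects.beta, theta=effects.theta,
                      alpha_tilde=effects.alpha_tilde / np.sqrt(k)),
            c / np.sqrt(k))


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit."""

    command: str
    config: dict
    seed: int | None
    time_unit: str = "seconds"
    created: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat())

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)
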