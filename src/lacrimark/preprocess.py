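"""Preprocessing of label-free proteomics feature tables.

The pipeline applies, in order: presence filtering per disease status,
log2 transformation, left-censored ("down-shifted normal") imputation of
missing values, and per-protein min-max scaling. Missingness in label-free
tear-fluid data is largely abundance-driven (MNAR): low-abundance proteins
fall below the detection limit, so missing entries are imputed from a normal
distribution shifted below the observed intensity distribution rather than
from its centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STATES = ("raw", "log2", "imputed", "scaled")
#: allowed processing-state transitions
_NEXT = {"raw": ("raw", "log2"), "log2": ("imputed",), "imputed": ("scaled",)}


@dataclass
class AbundanceMatrix:
    """Protein x sample intensity matrix with an explicit missingness mask.

    Parameters
    ----------
    values : pandas.DataFrame
        Proteins in rows, samples in columns. Masked cells hold NaN until
        imputation clears the mask.
    mask : pandas.DataFrame
        Boolean, same shape/labels as ``values``; True marks a missing cell.
    state : str
        One of ``raw``, ``log2``, ``imputed``, ``scaled``.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if not self.values.index.equals(self.mask.index) or not self.values.columns.equals(
            self.mask.columns
        ):
            raise ValueError("values and mask must share index and columns")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate protein ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.state in ("raw", "log2"):
            nan = self.values.isna()
            if not nan.equals(self.mask.astype(bool)):
                raise ValueError("mask must coincide with NaN cells before imputation")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, state: str = "raw") -> "AbundanceMatrix":
        """Build a matrix from a plain DataFrame; NaN cells become the mask."""
        return cls(values=df.astype(float), mask=df.isna(), state=state)

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values.copy(), self.mask.copy(), self.state)


def as_values_frame(matrix) -> pd.DataFrame:
    """Accept an AbundanceMatrix or a plain protein x sample DataFrame."""
    if isinstance(matrix, AbundanceMatrix):
        return matrix.values
    if isinstance(matrix, pd.DataFrame):
        return matrix
    raise TypeError(f"expected AbundanceMatrix or DataFrame, got {type(matrix).__name__}")


@dataclass(frozen=True)
class FilterParams:
    """Presence filter: a protein is kept if observed in at least
    ``min_presence_fraction_per_group`` of the samples of *every* group."""

    min_presence_fraction_per_group: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        f = self.min_presence_fraction_per_group
        if not (0.0 < f <= 1.0):
            raise ValueError("min_presence_fraction_per_group must be in (0, 1]")


@dataclass(frozen=True)
class ImputeParams:
    """Down-shifted normal imputation parameters.

    ``downshift`` and ``width`` are in units of the standard deviation of the
    observed values of the scope unit; defaults (1.8, 0.3) follow common
    practice for left-censored label-free data.
    """

    downshift: float = 1.8
    width: float = 0.3
    scope: str = "per_sample"  # or "global"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.downshift < 0:
            raise ValueError("downshift must be >= 0")
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.scope not in ("per_sample", "global"):
            raise ValueError("scope must be 'per_sample' or 'global'")


def _check_groups(m: AbundanceMatrix, groups: pd.Series) -> pd.Series:
    groups = pd.Series(groups)
    missing = m.samples.difference(groups.index)
    if len(missing):
        raise ValueError(f"samples without a group label: {list(missing)}")
    return groups.reindex(m.samples)


def filter_by_presence(
    m: AbundanceMatrix, groups: pd.Series, params: FilterParams | None = None
) -> AbundanceMatrix:
    """Retain proteins observed in >= the threshold fraction of every group.

    Protein order is preserved. ``groups`` maps sample id -> group label.
    """
    params = params or FilterParams()
    if m.state != "raw":
        raise ValueError(f"filter_by_presence expects state 'raw', got {m.state!r}")
    groups = _check_groups(m, groups)
    keep = pd.Series(True, index=m.proteins)
    thr = params.min_presence_fraction_per_group - 1e-12  # tolerate 36/54 == 2/3
    for g, cols in groups.groupby(groups).groups.items():
        if len(cols) == 0:
            raise ValueError(f"empty group {g!r}")
        observed_frac = (~m.mask.loc[:, list(cols)]).mean(axis=1)
        keep &= observed_frac >= thr
    idx = keep[keep].index
    return AbundanceMatrix(m.values.loc[idx], m.mask.loc[idx], state="raw")


def log2_transform(m: AbundanceMatrix) -> AbundanceMatrix:
    """log2 of observed entries; mask untouched; state raw -> log2."""
    if m.state != "raw":
        raise ValueError(f"log2_transform expects state 'raw', got {m.state!r}")
    obs = m.values.to_numpy()
    if np.any(obs[~m.mask.to_numpy()] <= 0):
        raise ValueError("non-positive observed intensity; cannot log2-transform")
    return AbundanceMatrix(np.log2(m.values), m.mask.copy(), state="log2")


def impute_mnar_downshift(m: AbundanceMatrix, params: ImputeParams | None = None) -> AbundanceMatrix:
    """Replace missing entries with draws from a down-shifted normal.

    For each scope unit (sample column by default) with observed mean ``mu``
    and SD ``sd``, missing entries are drawn i.i.d. from
    ``Normal(mu - downshift*sd, (width*sd)^2)``. Observed entries are left
    untouched, the mask is cleared and the state becomes ``imputed``.
    Deterministic for a fixed seed.
    """
    params = params or ImputeParams()
    if m.state != "log2":
        raise ValueError(f"impute_mnar_downshift expects state 'log2', got {m.state!r}")
    rng = np.random.default_rng(params.seed)
    values = m.values.to_numpy().copy()
    mask = m.mask.to_numpy()

    if params.scope == "global":
        units: list[tuple[str, np.ndarray, np.ndarray]] = [
            ("<global>", values.reshape(-1), mask.reshape(-1))
        ]
    else:
        units = [
            (str(m.samples[j]), values[:, j], mask[:, j]) for j in range(values.shape[1])
        ]
    for name, col, colmask in units:
        n_missing = int(colmask.sum())
        obs = col[~colmask]
        if n_missing == 0:
            continue
        if obs.size < 2:
            raise ValueError(f"scope unit {name!r} has fewer than 2 observed values")
        mu, sd = float(obs.mean()), float(obs.std(ddof=1))
        col[colmask] = rng.normal(mu - params.downshift * sd, params.width * sd, size=n_missing)

    out = pd.DataFrame(values, index=m.proteins, columns=m.samples)
    return AbundanceMatrix(out, pd.DataFrame(False, index=m.proteins, columns=m.samples), "imputed")


def minmax_scale(m: AbundanceMatrix) -> AbundanceMatrix:
    """Map each protein row to [0, 1] via (x - min)/(max - min).

    Constant rows map to all zeros (fixed convention).
    """
    if m.state != "imputed":
        raise ValueError(f"minmax_scale expects state 'imputed', got {m.state!r}")
    v = m.values.to_numpy()
    lo = v.min(axis=1, keepdims=True)
    hi = v.max(axis=1, keepdims=True)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(span > 0, (v - lo) / np.where(span > 0, span, 1.0), 0.0)
    out = pd.DataFrame(scaled, index=m.proteins, columns=m.samples)
    return AbundanceMatrix(out, m.mask.copy(), "scaled")


@dataclass(frozen=True)
class PreprocessParams:
    filter: FilterParams = field(default_factory=FilterParams)
    impute: ImputeParams = field(default_factory=ImputeParams)


def preprocess(
    m: AbundanceMatrix, groups: pd.Series, params: PreprocessParams | None = None, seed: int | None = None
) -> tuple[AbundanceMatrix, AbundanceMatrix]:
    """Full chain filter -> log2 -> impute -> scale.

    Returns ``(imputed, scaled)``: the imputed log2 matrix feeds differential
    abundance; the min-max scaled matrix feeds the classifiers.
    """
    params = params or PreprocessParams()
    impute_params = params.impute if seed is None else replace(params.impute, seed=seed)
    filtered = filter_by_presence(m, groups, params.filter)
    logged = log2_transform(filtered)
    imputed = impute_mnar_downshift(logged, impute_params)
    return imputed, minmax_scale(imputed)
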