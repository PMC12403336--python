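"""Synthetic tear-fluid proteomics data with recorded ground truth.

The generator emulates the structure of a two-cohort label-free DIA
experiment: per-protein log-normal intensities with planted group effects on
designated "signal" proteins, abundance-dependent (MNAR) dropout through a
logistic detection curve plus a small completely-at-random floor, a
six-protein densitometry panel with membrane batch structure, pooled
standards and occasional missing low bands, and a clinical table with
plausible demographic and disease fields. Ground truth (per-protein log2
fold changes, labels and the missingness parameters actually used) is always
returned alongside the data so parameter-recovery tests can score the
pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import AbundanceMatrix


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating model for a discovery-style cohort.

    Cohort-size defaults mirror a 49-case / 54-control discovery design.
    ``signal_proteins`` lists (protein id, log2 effect) pairs; effects are
    added to case samples, so a positive effect means more abundant in cases.
    """

    n_controls: int = 54
    n_cases: int = 49
    n_proteins: int = 1000
    signal_proteins: tuple = ()
    signal_base_log2: float | None = 21.0
    base_log2_mean_range: tuple = (12.0, 24.0)
    protein_sd: float = 1.0
    mnar_midpoint: float = 18.0  # log2 intensity of 50% detection
    mnar_slope: float = 0.8
    mcar_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 2 or self.n_cases < 2:
            raise ValueError("need at least 2 samples per group")
        if self.n_proteins < 1:
            raise ValueError("need at least one protein")
        if not (0.0 <= self.mcar_rate <= 1.0):
            raise ValueError("mcar_rate must be in [0, 1]")
        if self.protein_sd <= 0:
            raise ValueError("protein_sd must be positive")
        for name in ("protein_sd", "mnar_midpoint", "mnar_slope", "mcar_rate"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        lo, hi = self.base_log2_mean_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise ValueError("invalid base_log2_mean_range")
        ids = [p for p, _ in self.signal_proteins]
        if len(ids) != len(set(ids)):
            raise ValueError("signal protein ids must be distinct")
        known = set(protein_ids(self.n_proteins))
        unknown = set(ids) - known
        if unknown:
            raise ValueError(f"signal proteins outside the protein set: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """What the generator actually planted (the recovery oracle)."""

    true_log2fc: pd.Series  # per protein; 0 for non-signal proteins
    true_label: pd.Series  # per sample: "ALS" or "control"
    mnar_midpoint: float
    mnar_slope: float
    mcar_rate: float

    @property
    def signal_proteins(self) -> list[str]:
        return self.true_log2fc[self.true_log2fc != 0].index.tolist()

    def to_json(self, path) -> None:
        payload = {
            "true_log2fc": self.true_log2fc.to_dict(),
            "true_label": self.true_label.to_dict(),
            "mnar_midpoint": self.mnar_midpoint,
            "mnar_slope": self.mnar_slope,
            "mcar_rate": self.mcar_rate,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            true_log2fc=pd.Series(d["true_log2fc"]),
            true_label=pd.Series(d["true_label"]),
            mnar_midpoint=d["mnar_midpoint"],
            mnar_slope=d["mnar_slope"],
            mcar_rate=d["mcar_rate"],
        )


def protein_ids(n: int) -> list[str]:
    return [f"PROT_{i:04d}" for i in range(1, n + 1)]


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -700, 700)))


def generate_proteome(
    config: SyntheticConfig,
) -> tuple[AbundanceMatrix, pd.DataFrame, GroundTruth]:
    """Raw-scale intensity matrix, sample metadata and ground truth.

    Intensities are 2**(protein base + group effect + noise); a cell is
    missing when a Bernoulli detection draw with probability
    logistic((log2 intensity - mnar_midpoint) * mnar_slope) fails, or
    independently at the MCAR rate. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_controls + config.n_cases
    proteins = protein_ids(config.n_proteins)
    samples = [f"CTRL_{i:03d}" for i in range(1, config.n_controls + 1)] + [
        f"ALS_{i:03d}" for i in range(1, config.n_cases + 1)
    ]
    labels = pd.Series(
        ["control"] * config.n_controls + ["ALS"] * config.n_cases, index=samples, name="group"
    )

    lo, hi = config.base_log2_mean_range
    base = rng.uniform(lo, hi, size=config.n_proteins)
    effects = pd.Series(0.0, index=proteins)
    pos = {p: i for i, p in enumerate(proteins)}
    for pid, eff in config.signal_proteins:
        effects[pid] = float(eff)
        if config.signal_base_log2 is not None:
            # planted biomarkers sit in the consistently-detected regime
            base[pos[pid]] = config.signal_base_log2
    case = (labels == "ALS").to_numpy()
    log2_int = (
        base[:, None]
        + effects.to_numpy()[:, None] * case[None, :]
        + rng.normal(0.0, config.protein_sd, size=(config.n_proteins, n))
    )

    detect_p = _logistic((log2_int - config.mnar_midpoint) * config.mnar_slope)
    missing = rng.random(log2_int.shape) >= detect_p
    missing |= rng.random(log2_int.shape) < config.mcar_rate

    raw = np.power(2.0, log2_int)
    raw[missing] = np.nan
    values = pd.DataFrame(raw, index=proteins, columns=samples)
    matrix = AbundanceMatrix.from_dataframe(values, state="raw")
    metadata = pd.DataFrame({"sample": samples, "group": labels.to_numpy()}).set_index("sample")
    truth = GroundTruth(
        true_log2fc=effects,
        true_label=labels,
        mnar_midpoint=config.mnar_midpoint,
        mnar_slope=config.mnar_slope,
        mcar_rate=config.mcar_rate,
    )
    return matrix, metadata, truth


def generate_wb_panel(
    truth: GroundTruth,
    n_proteins: int = 6,
    membranes: int = 3,
    seed: int = 0,
    band_noise_sd: float = 0.15,
    membrane_scale_sd: float = 0.3,
    base_log2_abundance: float = 4.0,
    total_protein_range: tuple = (10.0, 60.0),
    missing_frac: float = 0.03,
    triplicates: int = 3,
    standard_intensity: float = 1000.0,
    return_truth: bool = False,
):
    """Long-format densitometry table for the first ``n_proteins`` signal
    proteins of ``truth``.

    Per sample, the true relative abundance is 2**(base + effect for cases +
    noise); the exported band intensity is abundance x membrane scale factor
    x multiplicative noise, averaged over triplicate lanes. Each membrane
    carries one pooled-standard intensity (scaled with the membrane). A small
    fraction of the lowest-abundance bands is set missing, emulating bands
    below the densitometry detection limit. Noise SDs are on the log2
    (band_noise_sd) and log (membrane_scale_sd) scales.
    """
    if membranes < 1:
        raise ValueError("membranes must be >= 1")
    signal = truth.signal_proteins
    if n_proteins > len(signal):
        raise ValueError("fewer signal proteins in truth than requested for the panel")
    rng = np.random.default_rng(seed)
    panel_proteins = signal[:n_proteins]
    samples = truth.true_label.index
    case = (truth.true_label == "ALS").to_numpy()
    membrane_of = np.arange(len(samples)) % membranes
    scale = np.exp(rng.normal(0.0, membrane_scale_sd, size=membranes))
    total_protein = rng.uniform(*total_protein_range, size=len(samples))

    rows = []
    truth_rows = {}
    for pid in panel_proteins:
        eff = truth.true_log2fc[pid]
        log2_ab = base_log2_abundance + eff * case + rng.normal(
            0.0, 1.0, size=len(samples)
        )
        abundance = np.power(2.0, log2_ab) * total_protein
        reps = abundance[None, :] * np.power(
            2.0, rng.normal(0.0, band_noise_sd, size=(triplicates, len(samples)))
        )
        band = reps.mean(axis=0) * scale[membrane_of]
        # left-censor: lowest-decile bands go missing at an elevated rate
        low = abundance <= np.quantile(abundance, 0.10)
        drop = low & (rng.random(len(samples)) < min(1.0, 10.0 * missing_frac))
        band = band.astype(float)
        band[drop] = np.nan
        truth_rows[pid] = abundance
        for j, s in enumerate(samples):
            rows.append(
                {
                    "protein": pid,
                    "sample": s,
                    "membrane": f"M{membrane_of[j] + 1}",
                    "band": band[j],
                    "standard": standard_intensity * scale[membrane_of[j]],
                    "total_protein": total_protein[j],
                }
            )
    records = pd.DataFrame(rows)
    if return_truth:
        true_abundance = pd.DataFrame(truth_rows, index=samples).T
        return records, true_abundance
    return records


def generate_clinical_table(n: int, seed: int = 0, delta_frs_fraction: float = 0.95,
                            case_fraction: float = 0.5) -> pd.DataFrame:
    """Plausible clinical records for ``n`` subjects.

    Wetting lengths respect the >= 5 mm inclusion rule; dFRS inputs
    (first recorded ALSFRS-R and months since onset) are present for a
    configurable fraction of cases. Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    n_cases = int(round(case_fraction * n))
    group = np.array(["ALS"] * n_cases + ["control"] * (n - n_cases))
    sex = rng.choice(["male", "female"], size=n)
    age = np.clip(rng.normal(62, 11, size=n).round(0), 25, 90)
    wl = np.clip(rng.gamma(2.5, 9.0, size=n).round(0), 5, 80)  # mm / 5 min
    collection = pd.Timestamp("2021-06-01") + pd.to_timedelta(
        rng.integers(0, 700, size=n), unit="D"
    )
    months_since_onset = np.where(group == "ALS", rng.gamma(3.0, 8.0, size=n) + 1.0, np.nan)
    onset = collection - pd.to_timedelta((months_since_onset * 30.4375).round(0), unit="D")
    diagnosis = collection - pd.to_timedelta(
        np.clip((months_since_onset * 0.5 * 30.4375).round(0), 0, None), unit="D"
    )
    alsfrs_coll = np.where(
        group == "ALS", np.clip(rng.normal(35, 6, size=n).round(0), 0, 48), np.nan
    )
    months_to_first = np.clip(months_since_onset * rng.uniform(0.3, 0.9, size=n), 0.5, None)
    alsfrs_first = np.clip(
        48 - rng.gamma(2.0, 4.0, size=n), alsfrs_coll, 48
    ).round(0)
    has_dfrs = (group == "ALS") & (rng.random(n) < delta_frs_fraction)
    fvc = np.where(group == "ALS", np.clip(rng.normal(80, 18, size=n).round(0), 20, 120), np.nan)
    pnfh = np.where(group == "ALS", rng.lognormal(np.log(2000), 0.6, size=n).round(0), np.nan)
    stratum = np.where(
        group == "ALS", rng.choice(["spinal", "bulbar"], size=n, p=[0.7, 0.3]), ""
    )
    df = pd.DataFrame(
        {
            "sample": [f"S{i:03d}" for i in range(1, n + 1)],
            "group": group,
            "sex": sex,
            "age": age,
            "wl_mm": wl,
            "onset_date": onset,
            "diagnosis_date": diagnosis,
            "collection_date": collection,
            "alsfrs_first": np.where(has_dfrs, alsfrs_first, np.nan),
            "months_onset_to_first_alsfrs": np.where(has_dfrs, months_to_first, np.nan),
            "alsfrs_collection": alsfrs_coll,
            "fvc_percent": fvc,
            "csf_pnfh_pg_ml": pnfh,
            "onset_stratum": stratum,
            "eye_disease": rng.random(n) < 0.2,
            "topical_substances": rng.random(n) < 0.08,
            "contact_lenses": rng.random(n) < 0.05,
        }
    ).set_index("sample")
    return df
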