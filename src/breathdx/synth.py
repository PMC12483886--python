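"""Synthetic breath-cohort generator.

Emulates the statistical structure of a GC-MS breathomics case/control
study so the full pipeline (QC -> screening -> modelling -> evaluation) can
be exercised with known ground truth:

* per-compound log-normal peak areas (multiplicative measurement noise);
* a planted subset of "true marker" compounds whose mean log10 area is
  shifted upward in malignant pre-operative samples;
* signal-to-noise ratios proportional to area over a compound-level noise
  draw, so low-abundance measurements tend to fall below the SNR validity
  gate;
* additional per-compound invalid-measurement probability (forced SNR
  below the gate);
* malignant subtype (lung cancer / thymoma / esophageal cancer), AJCC
  stage, paired post-operative samples with the planted effect attenuated,
  and low-sensitivity serum tumour markers.

Defaults follow the cohort structure of a 132-participant thoracic-lesion
study: 97 malignant vs 35 benign, 13 planted markers among 200 compounds,
per-compound effect sized so single-marker separability is AUC ~0.6 while
the combined 13-marker Bayes separability is ~0.84.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .tables import (
    PeakTable,
    SnrTable,
    SAMPLE_SHEET_COLUMNS,
    SERUM_MARKERS,
    validate_sample_sheet,
    write_matrix_tsv,
    write_sample_sheet,
)

__all__ = ["SyntheticConfig", "GroundTruth", "generate_cohort", "write_cohort"]

# fixed generator constants (documented in docs/methods.md)
_BASELINE_MEAN_RANGE = (4.5, 6.5)   # log10 area units
_BASELINE_SD_RANGE = (0.3, 0.5)     # log10 area units
_SNR_LOG_OFFSET = 1.8               # median log10 SNR above the validity gate
_SNR_NOISE_SD = 0.3                 # sd of compound noise on log10 scale
_SNR_GATE = 10.0
_BENIGN_SERUM_FPR = 0.02
_BENIGN_NODULE_FRACTION = 20 / 35   # benign nodules vs other benign lesions

_DEFAULT_SUBTYPE_PROPS = (77 / 97, 13 / 97, 7 / 97)          # LC, thymoma, EC
_DEFAULT_STAGE_PROPS = (4 / 97, 57 / 97, 13 / 97, 7 / 97, 13 / 97, 3 / 97)
_DEFAULT_SERUM_SENS = {"ca125": 0.061, "progrp": 0.121, "cea": 0.152,
                       "cyfra211": 0.242}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort; defaults mirror the emulated study."""

    n_malignant: int = 97
    n_benign: int = 35
    n_compounds: int = 200
    n_planted: int = 13
    effect_size: float = 0.3           # shift in log10 units on planted compounds
    snr_scale: float = 1.0
    missing_rate_range: tuple[float, float] = (0.0, 0.15)
    n_excluded: int = 9                # contaminants placed on the exclusion list
    subtype_props: tuple[float, ...] = _DEFAULT_SUBTYPE_PROPS
    stage_props: tuple[float, ...] = _DEFAULT_STAGE_PROPS
    postop_fraction: float = 0.55
    postop_effect_removal: float = 0.8
    serum_sensitivity: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SERUM_SENS))
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_malignant", "n_benign", "n_compounds", "n_planted"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_excluded < 0:
            raise ValueError("n_excluded must be non-negative")
        if self.n_planted > self.n_compounds:
            raise ValueError("n_planted exceeds n_compounds")
        if self.n_planted + self.n_excluded > self.n_compounds:
            raise ValueError("planted + excluded compounds exceed n_compounds")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.snr_scale <= 0:
            raise ValueError("snr_scale must be positive")
        lo, hi = self.missing_rate_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("missing_rate_range must be ordered fractions in [0,1]")
        for name in ("postop_fraction", "postop_effect_removal"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        for props, n in ((self.subtype_props, 3), (self.stage_props, 6)):
            if len(props) != n or abs(sum(props) - 1) > 1e-9 or min(props) < 0:
                raise ValueError("proportions must be non-negative and sum to 1")
        for m, s in self.serum_sensitivity.items():
            if m not in SERUM_MARKERS or not 0 <= s <= 1:
                raise ValueError(f"invalid serum sensitivity for {m!r}")
        # a cohort where every compound is expected to fail the 50% response
        # gate would make the whole pipeline vacuous
        best_snr_valid = 1 - _snr_invalid_prob(min(_BASELINE_SD_RANGE), self.snr_scale)
        if (1 - lo) * best_snr_valid < 0.5:
            raise ValueError(
                "missing_rate_range implies expected compound response < 50% "
                "for every compound; no compound could survive QC")


def _snr_invalid_prob(sigma: float, snr_scale: float) -> float:
    """P(SNR <= gate) for a non-forced measurement of a compound with area sd sigma.

    log10 SNR ~ N(log10(snr_scale) + offset, sqrt(sigma^2 + noise_sd^2)), since
    the compound baseline mean cancels between area and noise.
    """
    sd = float(np.hypot(sigma, _SNR_NOISE_SD))
    mean = np.log10(snr_scale) + _SNR_LOG_OFFSET
    return float(norm.cdf((np.log10(_SNR_GATE) - mean) / sd))


@dataclass
class GroundTruth:
    """What was planted: marker ids, contaminant ids, labels, design separability."""

    planted_compound_ids: list[str]
    excluded_compound_ids: list[str]
    per_sample_class: dict[str, str]
    per_sample_subtype: dict[str, str]
    per_sample_stage: dict[str, str]
    per_sample_timepoint: dict[str, str]
    design_auc: float

    def __post_init__(self) -> None:
        if set(self.planted_compound_ids) & set(self.excluded_compound_ids):
            raise ValueError("planted and excluded compound sets overlap")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _design_auc_mc(config: SyntheticConfig, base_mean, base_sd, planted_idx,
                   miss_rate, n_half: int = 1500) -> float:
    """Bayes-level separability of the observed planted features.

    Estimated by Monte-Carlo: draw a large balanced cohort of the planted
    compounds only, apply the same missingness/low-constant imputation the
    QC pipeline would produce, fit linear discriminant analysis on one half
    and measure its AUC on the other.  This is the ceiling a classifier
    could reach on the *generated* data (after measurement dropout), not
    the clean effect-size separability.  Recorded, never enforced.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    rng = np.random.default_rng([abs(int(config.seed)) % (2**31), 987654321])
    k = len(planted_idx)
    mu = base_mean[planted_idx]
    sd = base_sd[planted_idx]
    n = 2 * n_half
    y = np.repeat([1.0, 0.0], n_half)
    X = mu + config.effect_size * y[:, None] + rng.normal(0, 1, (n, k)) * sd
    inv_p = np.array([miss_rate[j] + (1 - miss_rate[j])
                      * _snr_invalid_prob(base_sd[j], config.snr_scale)
                      for j in planted_idx])
    invalid = rng.random((n, k)) < inv_p
    Xm = np.where(invalid, np.nan, X)
    low = np.nanmin(Xm, axis=0) + np.log10(0.5)   # half-minimum on log scale
    Xm = np.where(invalid, low, Xm)
    train = rng.permutation(n) < n_half
    m_, s_ = Xm[train].mean(0), Xm[train].std(0, ddof=1)
    s_[s_ == 0] = 1.0
    Z = (Xm - m_) / s_
    lda = LinearDiscriminantAnalysis().fit(Z[train], y[train])
    score = lda.decision_function(Z[~train])
    yo = y[~train].astype(bool)
    from scipy.stats import rankdata
    r = rankdata(score)
    n1, n0 = int(yo.sum()), int((~yo).sum())
    u = r[yo].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def generate_cohort(config: SyntheticConfig):
    """Draw a full synthetic cohort.

    Returns ``(PeakTable, SnrTable, sample_sheet, GroundTruth)``.  Identical
    configs (including the seed) produce bit-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    p = config.n_compounds

    compound_ids = [f"C{j + 1:04d}" for j in range(p)]
    special = rng.choice(p, size=config.n_planted + config.n_excluded, replace=False)
    planted_idx = np.sort(special[: config.n_planted])
    excluded_idx = np.sort(special[config.n_planted:])
    planted = [compound_ids[j] for j in planted_idx]
    excluded = [compound_ids[j] for j in excluded_idx]

    base_mean = rng.uniform(*_BASELINE_MEAN_RANGE, size=p)
    base_sd = rng.uniform(*_BASELINE_SD_RANGE, size=p)
    retention = pd.Series(np.sort(rng.uniform(2.0, 14.0, size=p)),
                          index=compound_ids, name="retention_time")
    miss_rate = rng.uniform(*config.missing_rate_range, size=p)

    # ----- subjects ---------------------------------------------------------
    n_subj = config.n_malignant + config.n_benign
    classes = ["malignant"] * config.n_malignant + ["benign"] * config.n_benign
    subtypes, stages = [], []
    for c in classes:
        if c == "malignant":
            subtypes.append(("LC", "thymoma", "EC")[
                rng.choice(3, p=np.asarray(config.subtype_props))])
            stages.append(("0", "I", "II", "III", "IV", "unknown")[
                rng.choice(6, p=np.asarray(config.stage_props))])
        else:
            subtypes.append("benign_nodule"
                            if rng.random() < _BENIGN_NODULE_FRACTION
                            else "benign_other")
            stages.append("unknown")
    has_post = rng.random(n_subj) < config.postop_fraction

    rows = []  # (sample_id, subject_idx, timepoint, pair_id)
    for i in range(n_subj):
        sid = f"S{i + 1:03d}"
        rows.append((sid, i, "preop", sid if has_post[i] else ""))
    for i in range(n_subj):
        if has_post[i]:
            rows.append((f"S{i + 1:03d}_post", i, "postop", f"S{i + 1:03d}"))

    # ----- matrices ---------------------------------------------------------
    n = len(rows)
    shift = np.zeros((n, p))
    for r, (_, i, tp, _) in enumerate(rows):
        if classes[i] == "malignant":
            s = config.effect_size
            if tp == "postop":
                s *= 1 - config.postop_effect_removal
            shift[r, planted_idx] = s
    log_area = base_mean + shift + rng.normal(0, 1, (n, p)) * base_sd
    areas = 10.0 ** log_area

    log_noise = (base_mean - _SNR_LOG_OFFSET) + rng.normal(0, _SNR_NOISE_SD, (n, p))
    snr = config.snr_scale * areas / 10.0 ** log_noise
    forced = rng.random((n, p)) < miss_rate
    snr = np.where(forced, rng.uniform(0, _SNR_GATE, (n, p)), snr)

    sample_ids = [r[0] for r in rows]
    peaks = PeakTable(pd.DataFrame(areas, index=sample_ids, columns=compound_ids),
                      retention_times=retention)
    snr_tab = SnrTable(pd.DataFrame(snr, index=sample_ids, columns=compound_ids))

    # ----- sample sheet -----------------------------------------------------
    marker_vals = {m: [] for m in SERUM_MARKERS}
    for sid, i, tp, _ in rows:
        for m, upper in SERUM_MARKERS.items():
            if tp == "postop":
                marker_vals[m].append(np.nan)
                continue
            rate = (config.serum_sensitivity.get(m, 0.0)
                    if classes[i] == "malignant" else _BENIGN_SERUM_FPR)
            if rng.random() < rate:
                marker_vals[m].append(round(upper * rng.uniform(1.1, 3.0), 2))
            else:
                marker_vals[m].append(round(upper * rng.uniform(0.2, 0.9), 2))
    sheet = pd.DataFrame({
        "sample_id": sample_ids,
        "class": [classes[i] for _, i, _, _ in rows],
        "subtype": [subtypes[i] for _, i, _, _ in rows],
        "stage": [stages[i] for _, i, _, _ in rows],
        "timepoint": [tp for _, _, tp, _ in rows],
        "pair_id": [pid for _, _, _, pid in rows],
        **marker_vals,
    })
    sheet = validate_sample_sheet(sheet)

    # ----- design separability ---------------------------------------------
    design_auc = _design_auc_mc(config, base_mean, base_sd, planted_idx,
                                miss_rate)

    truth = GroundTruth(
        planted_compound_ids=planted,
        excluded_compound_ids=excluded,
        per_sample_class={sid: classes[i] for sid, i, _, _ in rows},
        per_sample_subtype={sid: subtypes[i] for sid, i, _, _ in rows},
        per_sample_stage={sid: stages[i] for sid, i, _, _ in rows},
        per_sample_timepoint={sid: tp for sid, _, tp, _ in rows},
        design_auc=design_auc,
    )
    return peaks, snr_tab, sheet, truth


def write_cohort(peaks: PeakTable, snr: SnrTable, sheet: pd.DataFrame,
                 truth: GroundTruth, directory: str | Path,
                 overwrite: bool = False) -> dict[str, Path]:
    """Write the four cohort files (TSV matrices, CSV sheet, JSON truth)."""
    snr.check_aligned(peaks)
    sheet = validate_sample_sheet(sheet)
    if list(sheet["sample_id"]) != peaks.sample_ids:
        raise ValueError("sample sheet ids do not match the peak table")
    if set(truth.per_sample_class) != set(peaks.sample_ids):
        raise ValueError("ground-truth sample ids do not match the peak table")

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "peaks": directory / "peak_areas.tsv",
        "snr": directory / "snr.tsv",
        "sheet": directory / "sample_sheet.csv",
        "truth": directory / "ground_truth.json",
    }
    if not overwrite:
        for pth in paths.values():
            if pth.exists():
                raise FileExistsError(f"{pth} exists (pass overwrite=True)")
    write_matrix_tsv(peaks.areas, paths["peaks"])
    write_matrix_tsv(snr.snr, paths["snr"])
    write_sample_sheet(sheet, paths["sheet"])
    truth.to_json(paths["truth"])
    return paths
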