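"""Pre-analysis quality control and normalization of GC-MS peak tables.

Protocol, in fixed order:

1. **Validity gate** — a measurement is valid iff its SNR strictly exceeds
   10; missing SNR entries are invalid.
2. **Sample filter** — a sample's response rate is its valid fraction over
   all compounds; samples with rate >= 0.80 are retained.
3. **Compound filter** — compound response rates are computed over the
   retained samples only; compounds with rate >= 0.50 are retained ("valid
   VOC area matrix").  Invalid entries of the retained table are marked
   missing (NaN).
4. **Normalization** — missing entries imputed with half the minimum valid
   area of the compound (constants learned on reference samples), log10
   transform, per-sample median centering (robust correction for sample
   loading / instrument response), then per-compound z-scaling with mean/sd
   learned on the reference (training) samples only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import PeakTable, SnrTable

__all__ = ["SNR_MIN", "SAMPLE_RESPONSE_MIN", "COMPOUND_RESPONSE_MIN",
           "QcReport", "NormalizedMatrix", "compute_validity", "apply_qc",
           "normalize"]

SNR_MIN = 10.0
SAMPLE_RESPONSE_MIN = 0.80
COMPOUND_RESPONSE_MIN = 0.50


@dataclass
class QcReport:
    validity_mask: pd.DataFrame            # original axes, True = valid
    sample_response_rate: pd.Series        # over all compounds
    compound_response_rate: pd.Series      # over retained samples only
    retained_samples: list[str]
    retained_compounds: list[str]
    thresholds: tuple[float, float, float] = (SNR_MIN, SAMPLE_RESPONSE_MIN,
                                              COMPOUND_RESPONSE_MIN)

    def to_dict(self) -> dict:
        return {
            "thresholds": {"snr_min": self.thresholds[0],
                           "sample_min": self.thresholds[1],
                           "compound_min": self.thresholds[2]},
            "n_samples_in": int(self.validity_mask.shape[0]),
            "n_compounds_in": int(self.validity_mask.shape[1]),
            "retained_samples": self.retained_samples,
            "retained_compounds": self.retained_compounds,
            "sample_response_rate": self.sample_response_rate.round(6).to_dict(),
            "compound_response_rate": self.compound_response_rate.round(6).to_dict(),
        }


@dataclass
class NormalizedMatrix:
    """log10 -> median-centered -> z-scaled matrix plus its learned parameters."""

    values: pd.DataFrame
    reference_samples: list[str]
    impute_values: pd.Series      # half-minimum valid area per compound
    scale_mean: pd.Series
    scale_sd: pd.Series
    warnings: list[str] = field(default_factory=list)


def compute_validity(snr: SnrTable) -> pd.DataFrame:
    """Boolean mask: True iff SNR strictly exceeds the gate (NaN -> False)."""
    arr = snr.snr.to_numpy(dtype=float)
    mask = np.where(np.isnan(arr), False, arr > SNR_MIN)
    return pd.DataFrame(mask, index=snr.snr.index, columns=snr.snr.columns)


def apply_qc(peaks: PeakTable, snr: SnrTable) -> tuple[QcReport, PeakTable]:
    """Sample-then-compound response-rate filtering.

    Sample rates use all compounds; compound rates use retained samples
    only (the order matters and is fixed).  Boundary rates (exactly 0.80 /
    0.50) are retained.  Invalid entries of the output are set to NaN.
    """
    snr.check_aligned(peaks)
    mask = compute_validity(snr)

    sample_rate = mask.mean(axis=1)
    retained_samples = sample_rate.index[sample_rate >= SAMPLE_RESPONSE_MIN]
    if len(retained_samples) == 0:
        raise ValueError("no sample reaches the 80% response rate")

    compound_rate = mask.loc[retained_samples].mean(axis=0)
    retained_compounds = compound_rate.index[compound_rate >= COMPOUND_RESPONSE_MIN]
    if len(retained_compounds) == 0:
        raise ValueError("no compound reaches the 50% response rate")

    out = peaks.restrict(retained_samples, retained_compounds)
    out.areas = out.areas.where(mask.loc[retained_samples, retained_compounds])

    report = QcReport(
        validity_mask=mask,
        sample_response_rate=sample_rate,
        compound_response_rate=compound_rate,
        retained_samples=list(retained_samples),
        retained_compounds=list(retained_compounds),
    )
    return report, out


def normalize(peaks_valid: PeakTable, reference_samples: list[str],
              method: str = "median") -> NormalizedMatrix:
    """Impute, log10, center per sample, z-scale per compound.

    All learned constants (imputation values, z mean/sd) come from
    ``reference_samples`` only and are applied to every sample, so test
    samples never influence the training representation.  ``method`` picks
    the per-sample centering statistic: ``"median"`` (robust, default) or
    ``"total"`` (subtract the sample's mean log area, equivalent to
    total-signal normalization on the raw scale).
    """
    if method not in ("median", "total"):
        raise ValueError("method must be 'median' or 'total'")
    ref = list(reference_samples)
    if not ref or not set(ref) <= set(peaks_valid.sample_ids):
        raise ValueError("reference_samples must be a non-empty subset of the table")

    areas = peaks_valid.areas
    if (areas.to_numpy(dtype=float) <= 0).any():
        raise ValueError("non-missing areas must be strictly positive")

    msgs: list[str] = []
    impute = areas.loc[ref].min(axis=0) / 2.0
    dead = impute.index[~(impute > 0)]
    if len(dead):
        # compound never valid on the reference set: fall back to global minimum
        msgs.append(f"{len(dead)} compound(s) had no valid reference measurement")
        impute[dead] = areas.min(axis=0).reindex(dead).fillna(1.0) / 2.0

    filled = areas.fillna(impute)
    logged = np.log10(filled)
    center = logged.median(axis=1) if method == "median" else logged.mean(axis=1)
    centered = logged.sub(center, axis=0)

    mean = centered.loc[ref].mean(axis=0)
    sd = centered.loc[ref].std(axis=0, ddof=1)
    flat = sd.index[~(sd > 0)]
    if len(flat):
        msgs.append(f"{len(flat)} compound(s) had zero variance on the reference set")
        warnings.warn("zero-variance compound(s) on reference; sd set to 1",
                      stacklevel=2)
        sd[flat] = 1.0

    values = centered.sub(mean, axis=1).div(sd, axis=1)
    return NormalizedMatrix(values=values, reference_samples=ref,
                            impute_values=impute, scale_mean=mean,
                            scale_sd=sd, warnings=msgs)
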