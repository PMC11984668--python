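"""Sample- and probe-level quality control for methylation arrays.

Exclusion rules (defaults):

* a **sample** is excluded iff the fraction of its probes with
  detection p-value > 0.05 exceeds 5% ("more than 5%", strict) OR its
  bisulfite conversion rate is below 80%;
* a **probe** is excluded iff its bead count is below 3 in 5% or more
  of samples (inclusive) OR its mean detection p-value across samples
  exceeds 0.05 (strict).

Fractions are always evaluated on the original matrix, so sample and
probe filtering commute.  Missing detection p-values count as failures
and missing bead counts count as below threshold (conservative QC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BetaMatrix, ValidationError


@dataclass
class QCThresholds:
    sample_detp_cutoff: float = 0.05
    sample_detp_fraction: float = 0.05
    min_bisulfite_rate: float = 0.80
    probe_min_beadcount: int = 3
    probe_beadcount_fraction: float = 0.05
    probe_mean_detp_cutoff: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "sample_detp_cutoff",
            "sample_detp_fraction",
            "min_bisulfite_rate",
            "probe_beadcount_fraction",
            "probe_mean_detp_cutoff",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name}={v} outside (0, 1)")
        if self.probe_min_beadcount < 1:
            raise ValidationError("probe_min_beadcount must be >= 1")


def filter_samples(
    beta: BetaMatrix,
    manifest: pd.DataFrame,
    thresholds: QCThresholds | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Apply sample-level exclusions.

    Returns ``(kept sample ids, report)``; the report has one row per
    excluded sample with its failing metrics and reason(s).
    """
    t = thresholds or QCThresholds()
    if beta.detection_p is None:
        raise ValidationError("detection_p layer required for sample QC")
    meta = manifest.set_index("sample_id")
    unknown = beta.sample_ids.difference(meta.index)
    if len(unknown):
        raise ValidationError(
            f"samples in matrix but not manifest: {list(unknown[:5])}"
        )

    detp = beta.detection_p.to_numpy(dtype=float)
    failing = np.isnan(detp) | (detp > t.sample_detp_cutoff)
    frac_fail = failing.mean(axis=0)

    kept, rows = [], []
    for j, sid in enumerate(beta.sample_ids):
        reasons = []
        if frac_fail[j] > t.sample_detp_fraction:
            reasons.append("detection")
        bis = float(meta.loc[sid, "bisulfite_rate"])
        if bis < t.min_bisulfite_rate:
            reasons.append("bisulfite")
        if reasons:
            rows.append(
                {
                    "sample_id": sid,
                    "reason": "+".join(reasons),
                    "fail_detp_fraction": float(frac_fail[j]),
                    "bisulfite_rate": bis,
                }
            )
        else:
            kept.append(sid)
    report = pd.DataFrame(
        rows, columns=["sample_id", "reason", "fail_detp_fraction", "bisulfite_rate"]
    )
    return kept, report


def filter_probes(
    beta: BetaMatrix, thresholds: QCThresholds | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Apply probe-level exclusions.

    Returns ``(kept probe ids, report)``; the report has one row per
    excluded probe.
    """
    t = thresholds or QCThresholds()
    if beta.shape[0] == 0 or beta.shape[1] == 0:
        raise ValidationError("empty beta matrix")
    if beta.bead_count is None:
        raise ValidationError("bead_count layer required for probe QC")

    bead = beta.bead_count.to_numpy(dtype=float)
    low_bead = np.isnan(bead) | (bead < t.probe_min_beadcount)
    frac_low = low_bead.mean(axis=1)

    if beta.detection_p is not None:
        detp = beta.detection_p.to_numpy(dtype=float)
        mean_detp = np.where(np.isnan(detp), 1.0, detp).mean(axis=1)
    else:
        mean_detp = np.zeros(beta.shape[0])

    bead_bad = frac_low >= t.probe_beadcount_fraction  # "5% or more": inclusive
    detp_bad = mean_detp > t.probe_mean_detp_cutoff

    kept, rows = [], []
    for i, pid in enumerate(beta.probe_ids):
        reasons = []
        if bead_bad[i]:
            reasons.append("beadcount")
        if detp_bad[i]:
            reasons.append("detection")
        if reasons:
            rows.append(
                {
                    "probe_id": pid,
                    "reason": "+".join(reasons),
                    "low_bead_fraction": float(frac_low[i]),
                    "mean_detp": float(mean_detp[i]),
                }
            )
        else:
            kept.append(pid)
    report = pd.DataFrame(
        rows, columns=["probe_id", "reason", "low_bead_fraction", "mean_detp"]
    )
    return kept, report


def apply_qc(
    beta: BetaMatrix,
    manifest: pd.DataFrame,
    thresholds: QCThresholds | None = None,
) -> tuple[BetaMatrix, pd.DataFrame, pd.DataFrame]:
    """Run sample then probe QC (both evaluated on the original matrix).

    Returns the filtered matrix plus the two exclusion reports.
    """
    kept_samples, sample_report = filter_samples(beta, manifest, thresholds)
    kept_probes, probe_report = filter_probes(beta, thresholds)
    return beta.subset(probes=kept_probes, samples=kept_samples), sample_report, probe_report
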