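"""Probe- and sample-level quality control for methylation beta matrices.

Two filter profiles are provided:

* brain-style: (1) drop samples in which >1% of probes have detection
  p > 0.05, then (2) drop probes with beadcount < 3 in >5% of the
  remaining samples, then (3) drop probes with >1% of the remaining
  samples at detection p > 0.05. Inequalities are strict, matching the
  printed thresholds.
* blood-style: drop probes with a detection rate below 95% at p < 0.01,
  then drop samples whose count of probes detected at p < 0.01 falls
  below an absolute threshold (450,000 on a full 485,512-probe array;
  rescaled proportionally for smaller matrices so the rule stays testable
  at fixture scale — the scaling factor is logged).

All filters are pure: they return a new matrix plus a QcReport and are
idempotent. Rule order is applied exactly as documented above.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bloodbrain.io import BetaMatrix, SampleSheet

logger = logging.getLogger(__name__)

#: Probe count of the full 450K array the absolute blood call-rate
#: threshold was defined against.
REFERENCE_ARRAY_PROBES = 485_512

SAMPLE_REASONS = ("high_detp_fraction", "low_call_rate", "sex_mismatch")
PROBE_REASONS = ("detp", "beadcount", "blacklist", "low_detection_rate")


@dataclass
class QcThresholds:
    """Thresholds for the QC rules; defaults mirror the published pipeline."""

    probe_detection_p_max: float = 0.05
    probe_fail_sample_frac: float = 0.01
    sample_fail_probe_frac: float = 0.01
    beadcount_min: int = 3
    beadcount_fail_sample_frac: float = 0.05
    blood_probe_call_rate_min: float = 0.95
    blood_detection_p: float = 0.01
    blood_sample_min_probes: int = 450_000

    def __post_init__(self) -> None:
        for name in (
            "probe_detection_p_max",
            "probe_fail_sample_frac",
            "sample_fail_probe_frac",
            "beadcount_fail_sample_frac",
            "blood_probe_call_rate_min",
            "blood_detection_p",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.beadcount_min < 0:
            raise ValueError("beadcount_min must be >= 0")
        if self.blood_sample_min_probes < 0:
            raise ValueError("blood_sample_min_probes must be >= 0")


@dataclass
class Removal:
    axis: str  # "sample" | "probe"
    id: str
    reason: str
    rule_value: float
    threshold: float


@dataclass
class QcReport:
    """Record of removals, one primary reason each (first rule that fired)."""

    removals: list[Removal] = field(default_factory=list)
    n_probes_before: int = 0
    n_probes_after: int = 0
    n_samples_before: int = 0
    n_samples_after: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def removed_samples(self) -> list[Removal]:
        return [r for r in self.removals if r.axis == "sample"]

    @property
    def removed_probes(self) -> list[Removal]:
        return [r for r in self.removals if r.axis == "probe"]

    def warn(self, msg: str) -> None:
        self.warnings.append(msg)
        logger.warning(msg)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"axis": r.axis, "id": r.id, "reason": r.reason, "rule_value": r.rule_value, "threshold": r.threshold}
            for r in self.removals
        ]
        return pd.DataFrame(rows, columns=["axis", "id", "reason", "rule_value", "threshold"])

    def check_counts(self) -> None:
        """Assert removed + retained = input on both axes."""
        assert self.n_probes_before - len(self.removed_probes) == self.n_probes_after
        assert self.n_samples_before - len(self.removed_samples) == self.n_samples_after


def _new_report(m: BetaMatrix) -> QcReport:
    return QcReport(
        n_probes_before=m.shape[0],
        n_probes_after=m.shape[0],
        n_samples_before=m.shape[1],
        n_samples_after=m.shape[1],
    )


def filter_brain_qc(m: BetaMatrix, t: QcThresholds | None = None) -> tuple[BetaMatrix, QcReport]:
    """Brain-array QC: failing samples, then beadcount probes, then
    detection-p probes, in that order."""
    t = t or QcThresholds()
    report = _new_report(m)

    # (1) samples with >1% probes at det-p > 0.05
    if m.detection_p is not None:
        detp = m.detection_p.to_numpy(dtype=float)
        fail = detp > t.probe_detection_p_max  # NaN compares False: missing det-p never counts as failure
        frac_per_sample = fail.mean(axis=0)
        keep_mask = frac_per_sample <= t.sample_fail_probe_frac
        for j in np.flatnonzero(~keep_mask):
            report.removals.append(
                Removal("sample", m.sample_ids[j], "high_detp_fraction", float(frac_per_sample[j]), t.sample_fail_probe_frac)
            )
        m = m.subset(samples=[s for s, k in zip(m.sample_ids, keep_mask) if k])
    else:
        report.warn("detection_p matrix absent: sample and probe detection rules skipped")

    # (2) probes with beadcount < 3 in >5% of remaining samples
    if m.beadcount is not None:
        if m.shape[1] > 0:
            bead = m.beadcount.to_numpy(dtype=float)
            low = bead < t.beadcount_min
            frac_per_probe = low.mean(axis=1)
            keep_mask = frac_per_probe <= t.beadcount_fail_sample_frac
            for i in np.flatnonzero(~keep_mask):
                report.removals.append(
                    Removal("probe", m.probe_ids[i], "beadcount", float(frac_per_probe[i]), t.beadcount_fail_sample_frac)
                )
            m = m.subset(probes=[p for p, k in zip(m.probe_ids, keep_mask) if k])
    else:
        report.warn("beadcount matrix absent: beadcount rule skipped")

    # (3) probes with >1% of remaining samples at det-p > 0.05
    if m.detection_p is not None and m.shape[1] > 0:
        detp = m.detection_p.to_numpy(dtype=float)
        fail = detp > t.probe_detection_p_max
        frac_per_probe = fail.mean(axis=1)
        keep_mask = frac_per_probe <= t.probe_fail_sample_frac
        for i in np.flatnonzero(~keep_mask):
            report.removals.append(
                Removal("probe", m.probe_ids[i], "detp", float(frac_per_probe[i]), t.probe_fail_sample_frac)
            )
        m = m.subset(probes=[p for p, k in zip(m.probe_ids, keep_mask) if k])

    report.n_probes_after, report.n_samples_after = m.shape
    report.check_counts()
    return m, report


def filter_blood_qc(m: BetaMatrix, t: QcThresholds | None = None) -> tuple[BetaMatrix, QcReport]:
    """Blood-array QC: low-detection-rate probes, then low-call-rate samples."""
    t = t or QcThresholds()
    report = _new_report(m)
    if m.detection_p is None:
        report.warn("detection_p matrix absent: blood QC rules skipped")
        return m, report

    n_input_probes = m.shape[0]

    # (1) probes with detection rate < 95% at p < 0.01
    detp = m.detection_p.to_numpy(dtype=float)
    detected = detp < t.blood_detection_p
    rate_per_probe = detected.mean(axis=1) if m.shape[1] > 0 else np.ones(m.shape[0])
    keep_mask = rate_per_probe >= t.blood_probe_call_rate_min
    for i in np.flatnonzero(~keep_mask):
        report.removals.append(
            Removal("probe", m.probe_ids[i], "low_detection_rate", float(rate_per_probe[i]), t.blood_probe_call_rate_min)
        )
    m = m.subset(probes=[p for p, k in zip(m.probe_ids, keep_mask) if k])

    # (2) samples detecting fewer than the (possibly rescaled) absolute count
    threshold = float(t.blood_sample_min_probes)
    if n_input_probes < REFERENCE_ARRAY_PROBES:
        scale = n_input_probes / REFERENCE_ARRAY_PROBES
        threshold = t.blood_sample_min_probes * scale
        report.warn(
            f"call-rate threshold rescaled by {scale:.6g} for a {n_input_probes}-probe matrix: "
            f"{threshold:.1f} probes"
        )
    detp = m.detection_p.to_numpy(dtype=float) if m.shape[0] > 0 else np.empty((0, m.shape[1]))
    counts = (detp < t.blood_detection_p).sum(axis=0)
    keep_mask = counts >= threshold
    for j in np.flatnonzero(~keep_mask):
        report.removals.append(Removal("sample", m.sample_ids[j], "low_call_rate", float(counts[j]), threshold))
    m = m.subset(samples=[s for s, k in zip(m.sample_ids, keep_mask) if k])

    report.n_probes_after, report.n_samples_after = m.shape
    report.check_counts()
    return m, report


def check_sex(m: BetaMatrix, sheet: SampleSheet, x_probe_ids: set[str], min_separation: float = 0.05) -> QcReport:
    """Flag samples whose methylation-predicted sex disagrees with the
    recorded sex.

    Sex is predicted by a deterministic 1-D 2-means split of the per-sample
    mean beta over X-linked probes; the higher-mean cluster is called female
    (X-inactivation leaves females with intermediate X methylation). Samples
    with recorded sex ``unknown`` are exempt. If the cluster separation is
    below ``min_separation`` mean-beta units the cohort is treated as
    single-sex and no flags are raised.

    Returns a QcReport fragment; it does not remove samples itself.
    """
    report = _new_report(m)
    x_present = [p for p in x_probe_ids if p in m.values.index]
    if not x_present:
        raise ValueError("no X-linked probes present in matrix")
    if m.shape[1] < 2:
        report.warn("fewer than 2 samples: sex prediction skipped")
        return report

    mean_x = m.values.loc[x_present].mean(axis=0, skipna=True)  # per sample
    lo, hi = _two_means_1d(mean_x.to_numpy(dtype=float))
    if hi - lo < min_separation:
        report.warn(f"X-probe cluster separation {hi - lo:.4f} < {min_separation}: single-sex cohort assumed, sex check skipped")
        return report

    recorded = sheet.frame.set_index("sample_id")["recorded_sex"]
    for sample, mu in mean_x.items():
        predicted = "F" if abs(mu - hi) <= abs(mu - lo) else "M"
        rec = recorded.get(sample, "unknown")
        if rec in ("F", "M") and rec != predicted:
            report.removals.append(Removal("sample", str(sample), "sex_mismatch", float(mu), (lo + hi) / 2))
    # flags only: the caller decides whether to drop the samples
    return report


def _two_means_1d(x: np.ndarray) -> tuple[float, float]:
    """Deterministic Lloyd's algorithm in 1-D, centers initialized at
    min/max; returns (low_center, high_center)."""
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        return lo, hi
    for _ in range(100):
        assign_hi = np.abs(x - hi) <= np.abs(x - lo)
        new_lo = float(x[~assign_hi].mean()) if (~assign_hi).any() else lo
        new_hi = float(x[assign_hi].mean()) if assign_hi.any() else hi
        if new_lo == lo and new_hi == hi:
            break
        lo, hi = new_lo, new_hi
    return lo, hi


def apply_blacklist(m: BetaMatrix, blacklist: set[str]) -> tuple[BetaMatrix, QcReport]:
    """Remove blacklisted probes (e.g. SNP and cross-hybridising probes);
    ids absent from the matrix are ignored with a warning."""
    report = _new_report(m)
    present = [p for p in m.probe_ids if p in blacklist]
    absent = blacklist - set(m.probe_ids)
    if absent:
        report.warn(f"{len(absent)} blacklisted probe(s) not present in matrix")
    for p in present:
        report.removals.append(Removal("probe", p, "blacklist", float("nan"), float("nan")))
    keep = [p for p in m.probe_ids if p not in blacklist]
    m = m.subset(probes=keep)
    report.n_probes_after, report.n_samples_after = m.shape
    report.check_counts()
    return m, report
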