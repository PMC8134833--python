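"""Projection of predictor weight tables onto beta matrices.

The score for sample *i* under weight table *w* is

    score_i = intercept + sum_j w_j * beta_ij

summed over the weight-table CpGs that are present in the matrix and
non-missing for that sample. Terms are dropped, never rescaled: rescaling
would change the units of the score relative to the published predictors.
Per-sample coverage (CpGs used / CpGs in the table) is reported so that
callers can judge; samples below ``min_coverage`` are warned about but
never dropped.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from bloodbrain.io import BetaMatrix, WeightTable

logger = logging.getLogger(__name__)

#: The single strongest blood methylation correlate of smoking (AHRR locus).
SMOKING_CPG = "cg05575921"


def harmonize_platforms(matrices: list[BetaMatrix], restrict_to: set[str] | None = None) -> list[BetaMatrix]:
    """Subset all matrices to their common probe set (optionally further
    intersected with ``restrict_to``, e.g. a 450K probe list).

    Probe order follows the first matrix. Raises if the intersection is
    empty.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    common = set(matrices[0].probe_ids)
    for m in matrices[1:]:
        common &= set(m.probe_ids)
    if restrict_to is not None:
        common &= set(restrict_to)
    if not common:
        raise ValueError("empty probe intersection across matrices")
    order = [p for p in matrices[0].probe_ids if p in common]
    logger.info("harmonized %d matrices to %d common probes", len(matrices), len(order))
    return [m.subset(probes=order) for m in matrices]


def project_scores(m: BetaMatrix, w: WeightTable, min_coverage: float = 0.95) -> pd.DataFrame:
    """Project a weight table onto a beta matrix.

    Returns a tidy score table with columns ``sample_id``, ``trait``,
    ``score``, ``n_cpgs_used``, ``coverage``. Missing cells and absent
    probes are treated identically: the term is dropped and coverage is
    accounted per sample.
    """
    overlap = [p for p in w.probe_ids if p in m.values.index]
    if not overlap:
        raise ValueError(f"no CpGs of the {w.trait!r} weight table are present in the matrix")

    betas = m.values.loc[overlap]  # overlap x samples
    weights = w.weights.loc[overlap].to_numpy(dtype=float)
    arr = betas.to_numpy(dtype=float)
    present = ~np.isnan(arr)
    scores = w.intercept + np.nansum(weights[:, None] * arr, axis=0)
    n_used = present.sum(axis=0)
    coverage = n_used / len(w)

    out = pd.DataFrame(
        {
            "sample_id": m.sample_ids,
            "trait": w.trait,
            "score": scores,
            "n_cpgs_used": n_used.astype(int),
            "coverage": coverage,
        }
    )
    low = out[out["coverage"] < min_coverage]
    for _, row in low.iterrows():
        logger.warning(
            "sample %s: %s score coverage %.3f below %.2f (%d/%d CpGs)",
            row["sample_id"], w.trait, row["coverage"], min_coverage, row["n_cpgs_used"], len(w),
        )
    return out


def extract_cpg(m: BetaMatrix, probe_id: str = SMOKING_CPG) -> pd.DataFrame:
    """Per-sample beta at a single probe (default cg05575921).

    Returns columns ``sample_id``, ``probe_id``, ``beta``; samples with a
    missing cell at the probe are omitted. An absent probe yields an empty
    table with a logged warning.
    """
    cols = ["sample_id", "probe_id", "beta"]
    if probe_id not in m.values.index:
        logger.warning("probe %s absent from matrix", probe_id)
        return pd.DataFrame(columns=cols)
    row = m.values.loc[probe_id]
    out = pd.DataFrame({"sample_id": row.index, "probe_id": probe_id, "beta": row.to_numpy(dtype=float)})
    return out.dropna(subset=["beta"]).reset_index(drop=True)
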