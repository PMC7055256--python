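"""SNP-diversity trajectories and replicate aggregation.

Genetic diversity over cycles is tracked on principal axes of the founder SNP
dosage matrix (centered, not variance-scaled; with Euclidean distances on
centered dosages, principal coordinates and principal components coincide up
to scale).  The axes are fitted once on the founder generation and every
later cycle is projected onto them, so PC1 scores are comparable across the
whole 30-cycle trajectory: as reciprocal recurrent selection drives the two
pools apart, their PC1 ranges separate and each pool's within-range spread
contracts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DiversityProjection",
    "fit_diversity_axes",
    "project_population",
    "pool_pc1_summary",
    "records_to_frame",
    "aggregate_replicates",
]

STATISTICS = ("inbred_mean", "inbred_var", "hybrid_mean", "hybrid_var",
              "pc1_min", "pc1_mean", "pc1_max")


@dataclass(frozen=True)
class DiversityProjection:
    """Fixed principal axes of a reference population's SNP dosages.

    ``loadings`` is (n_snp, n_axes) with unit-norm columns;
    ``reference_center`` the per-SNP mean dosage of the reference population.
    Reference scores have zero mean on each axis by construction.
    """

    loadings: np.ndarray
    reference_center: np.ndarray
    reference_scores: np.ndarray

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.loadings, axis=0)
        if not np.allclose(norms, 1.0):
            raise ValueError("axis loadings must have unit norm")


def fit_diversity_axes(reference_dosages: np.ndarray, n_axes: int = 2) -> DiversityProjection:
    """Principal axes of the centered reference SNP dosage matrix.

    Sign of each axis is canonicalized so the lowest-index individual with a
    nonzero score scores non-negative.
    """
    x = np.asarray(reference_dosages, dtype=np.float64)
    center = x.mean(axis=0)
    xc = x - center
    if not np.any(xc):
        raise ValueError("reference population is constant at every SNP")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    n_axes = min(n_axes, s.size)
    loadings = vt[:n_axes].T.copy()
    scores = u[:, :n_axes] * s[:n_axes]
    for j in range(n_axes):
        nz = np.flatnonzero(np.abs(scores[:, j]) > 1e-12 * max(s[0], 1.0))
        if nz.size and scores[nz[0], j] < 0:
            scores[:, j] = -scores[:, j]
            loadings[:, j] = -loadings[:, j]
    return DiversityProjection(loadings=loadings, reference_center=center,
                               reference_scores=scores)


def project_population(dosages: np.ndarray, proj: DiversityProjection) -> np.ndarray:
    """Project SNP dosages onto the fixed reference axes.

    The reference population reproduces its fit scores exactly; any other
    population is placed on the same coordinate system, which is what makes
    cross-cycle diversity trajectories meaningful.
    """
    x = np.atleast_2d(np.asarray(dosages, dtype=np.float64))
    if x.shape[1] != proj.loadings.shape[0]:
        raise ValueError(
            f"dosage matrix has {x.shape[1]} SNP columns, projection expects "
            f"{proj.loadings.shape[0]}")
    return (x - proj.reference_center) @ proj.loadings


def pool_pc1_summary(scores: np.ndarray, pools: np.ndarray,
                     ) -> dict[str, tuple[float, float, float]]:
    """(min, mean, max) of PC1 scores per pool label."""
    scores = np.asarray(scores, dtype=np.float64)
    pools = np.asarray(pools)
    out: dict[str, tuple[float, float, float]] = {}
    for label in np.unique(pools):
        s = scores[pools == label]
        if s.size == 0:
            raise ValueError(f"pool {label!r} is empty")
        out[str(label)] = (float(s.min()), float(s.mean()), float(s.max()))
    return out


def records_to_frame(records: Sequence, replicate: int, strategy: str,
                     n_qtn: int, dom_mean: float) -> pd.DataFrame:
    """Tidy per-cycle rows (one row per pool per cycle) from CycleRecords."""
    rows = []
    for rec in records:
        pools = sorted(rec.pool_pc1) if rec.pool_pc1 else ["all"]
        for pool in pools:
            pc1 = rec.pool_pc1.get(pool, (np.nan, np.nan, np.nan))
            rows.append({
                "replicate": replicate, "strategy": strategy, "n_qtn": n_qtn,
                "dom_mean": dom_mean, "cycle": rec.cycle,
                "inbred_mean": rec.inbred_mean, "inbred_var": rec.inbred_var,
                "hybrid_mean": rec.hybrid_mean, "hybrid_var": rec.hybrid_var,
                "pool": pool, "pc1_min": pc1[0], "pc1_mean": pc1[1], "pc1_max": pc1[2],
            })
    return pd.DataFrame(rows)


def aggregate_replicates(raw: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD (n-1 denominator) over replicates of every trajectory statistic.

    Input is the tidy per-cycle table; output is keyed by
    (strategy, n_qtn, dom_mean, cycle, pool) with ``<stat>_mean`` and
    ``<stat>_sd`` columns.  Raises if any cell is missing replicates relative
    to the rest of the table.
    """
    keys = ["strategy", "n_qtn", "dom_mean", "cycle", "pool"]
    counts = raw.groupby(keys, sort=True)["replicate"].nunique()
    if counts.min() < 2:
        bad = counts[counts < 2].index[0]
        raise ValueError(f"cell {bad} has fewer than 2 replicates")
    if counts.nunique() != 1:
        bad = counts[counts != counts.max()].index[0]
        raise ValueError(f"ragged replicate sets: cell {bad} has {counts.min()} "
                         f"of {counts.max()} replicates")
    stats = [s for s in STATISTICS if s in raw.columns]
    agg = raw.groupby(keys, sort=True)[stats].agg(["mean", lambda v: v.std(ddof=1)])
    agg.columns = [f"{stat}_{'sd' if fn == '<lambda_0>' else fn}" for stat, fn in agg.columns]
    return agg.reset_index()
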