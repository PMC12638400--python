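"""Observer scores and the agreement statistics layer.

Volumes are scored by several raters on a 1-5 Likert scale (5 = artifact
free, 1 = non-diagnostic).  Radiologists' scores enter the per-volume
average with double weight relative to radiographers, reflecting their
greater reading experience.  Inter-rater reliability is summarised by
Krippendorff's alpha (ordinal by default), the metric-observer association
by the Spearman rank correlation with a two-sided p-value, and metrics are
ranked per sequence by |rho| and summarised by their median rank.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RatingTable",
    "AgreementReport",
    "weighted_mean_score",
    "krippendorff_alpha",
    "spearman",
    "significance_filter",
    "median_rank",
]

DEFAULT_ROLE_WEIGHTS = {"radiologist": 2.0, "radiographer": 1.0}
DEFAULT_MC_SEED = 20250610


@dataclass
class RatingTable:
    """Ordinal scores indexed (volume, rater), with per-rater roles/weights.

    ``scores`` is a DataFrame (rows = volume ids, columns = rater ids) with
    NaN marking missing ratings.  Weights default to 2 for radiologists and
    1 for radiographers.
    """

    scores: pd.DataFrame
    roles: Dict[str, str]
    weights: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        self.scores = self.scores.astype(float)
        vals = self.scores.to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 1 or finite.max() > 5):
            raise ValueError("scores must lie in 1..5")
        if self.scores.notna().sum(axis=1).min() < 1:
            raise ValueError("every volume needs at least one score")
        missing = set(self.scores.columns) - set(self.roles)
        if missing:
            raise ValueError(f"raters without a role: {sorted(missing)}")
        if self.weights is None:
            self.weights = {r: DEFAULT_ROLE_WEIGHTS[self.roles[r]]
                            for r in self.scores.columns}
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("rater weights must be positive")

    @classmethod
    def from_tidy(cls, df: pd.DataFrame) -> "RatingTable":
        """Build from long-format rows (volume_id, rater_id, role, score)."""
        wide = df.pivot(index="volume_id", columns="rater_id", values="score")
        roles = df.drop_duplicates("rater_id").set_index("rater_id")["role"].to_dict()
        return cls(scores=wide, roles=roles)

    def to_tidy(self) -> pd.DataFrame:
        out = (self.scores.reset_index(names="volume_id")
               .melt(id_vars="volume_id", var_name="rater_id", value_name="score")
               .dropna(subset=["score"]))
        out["role"] = out["rater_id"].map(self.roles)
        return out.sort_values(["volume_id", "rater_id"]).reset_index(drop=True)


def weighted_mean_score(table: RatingTable) -> pd.Series:
    """Per-volume weighted mean score; missing raters drop from both sums."""
    w = pd.Series(table.weights)[table.scores.columns]
    present = table.scores.notna()
    num = (table.scores.fillna(0.0) * w).sum(axis=1)
    den = (present * w).sum(axis=1)
    return num / den


def _ordinal_delta(n_marginal: np.ndarray) -> np.ndarray:
    """Squared ordinal distances between value categories.

    delta(c, k) = (sum of marginal counts of the categories between c and k,
    counting the endpoints at half weight)^2 -- categories far apart in the
    observed ordinal scale, or separated by heavily used categories, count
    as larger disagreements.
    """
    v = len(n_marginal)
    cum = np.concatenate([[0.0], np.cumsum(n_marginal)])
    delta = np.zeros((v, v))
    for c in range(v):
        for k in range(c + 1, v):
            between = cum[k + 1] - cum[c]
            d = between - (n_marginal[c] + n_marginal[k]) / 2.0
            delta[c, k] = delta[k, c] = d * d
    return delta


def krippendorff_alpha(scores: np.ndarray | pd.DataFrame,
                       level: str = "ordinal") -> float:
    """Krippendorff's alpha via the coincidence-matrix formulation.

    ``scores`` is (units x raters) with NaN for missing ratings.  Units with
    fewer than two ratings cannot form pairs and are ignored.  ``level``
    selects the disagreement metric: ``nominal``, ``interval`` or
    ``ordinal`` (appropriate for Likert data).
    """
    arr = np.asarray(scores, dtype=float)
    if arr.ndim != 2:
        raise ValueError("scores must be 2D (units x raters)")
    units = [row[np.isfinite(row)] for row in arr]
    units = [u for u in units if u.size >= 2]
    if not units:
        raise ValueError("need at least one unit rated by >= 2 raters")
    values = np.unique(np.concatenate(units))
    if values.size < 2:
        raise ValueError("all ratings identical: expected disagreement is zero")
    index = {v: i for i, v in enumerate(values)}
    v = values.size

    coincidence = np.zeros((v, v))
    for u in units:
        m_u = u.size
        idx = np.array([index[x] for x in u])
        counts = np.bincount(idx, minlength=v).astype(float)
        pair_matrix = np.outer(counts, counts) - np.diag(counts)
        coincidence += pair_matrix / (m_u - 1)
    n_marginal = coincidence.sum(axis=1)
    n_total = n_marginal.sum()

    if level == "nominal":
        delta = 1.0 - np.eye(v)
    elif level == "interval":
        delta = (values[:, None] - values[None, :]) ** 2
    elif level == "ordinal":
        delta = _ordinal_delta(n_marginal)
    else:
        raise ValueError(f"unknown level {level!r}")

    d_observed = float((coincidence * delta).sum())
    d_expected = float((np.outer(n_marginal, n_marginal) * delta).sum()
                       / (n_total - 1))
    if d_expected == 0.0:
        raise ValueError("expected disagreement is zero: alpha undefined")
    return 1.0 - d_observed / d_expected


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx ** 2).sum()) * float((ry ** 2).sum()))
    if denom == 0.0:
        raise ValueError("constant vector: Spearman rho undefined")
    return float((rx * ry).sum() / denom)


def spearman(x: Iterable[float], y: Iterable[float],
             seed: int = DEFAULT_MC_SEED, n_resamples: int = 10_000,
             ) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of mid-ranks (ties get average ranks).
    The p-value is exact (full permutation enumeration) for n <= 8, a seeded
    Monte-Carlo permutation estimate for 8 < n <= 20, and the usual
    t-distribution approximation for larger n.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D and equally long")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant vector: Spearman rho undefined")
    rx, ry = _midranks(x), _midranks(y)
    rho = _rho_from_ranks(rx, ry)
    tol = 1e-12

    if n <= 8:
        count = total = 0
        for perm in itertools.permutations(range(n)):
            r = _rho_from_ranks(rx, ry[list(perm)])
            total += 1
            if abs(r) >= abs(rho) - tol:
                count += 1
        return rho, count / total

    if n <= 20:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_resamples):
            r = _rho_from_ranks(rx, rng.permutation(ry))
            if abs(r) >= abs(rho) - tol:
                count += 1
        return rho, (count + 1) / (n_resamples + 1)

    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho ** 2))
    return rho, float(2 * stats.t.sf(abs(t), df=n - 2))


@dataclass
class AgreementReport:
    """Spearman rho/p per (metric, sequence), alpha per sequence, median ranks.

    ``rho`` and ``p`` are DataFrames with metrics as rows and sequences as
    columns; ``n`` holds the per-cell number of volumes that entered the
    correlation after dropping undefined metric values.
    """

    rho: pd.DataFrame
    p: pd.DataFrame
    alpha: pd.Series
    n: Optional[pd.DataFrame] = None
    alpha_level_of_measurement: str = "ordinal"
    median_ranks: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.median_ranks is None:
            self.median_ranks = median_rank(self.rho)
        finite = self.rho.to_numpy()[np.isfinite(self.rho.to_numpy())]
        if finite.size and np.abs(finite).max() > 1 + 1e-9:
            raise ValueError("|rho| must not exceed 1")

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for metric in self.rho.index:
            for seq in self.rho.columns:
                rows.append({"metric": metric, "sequence": seq,
                             "rho": self.rho.loc[metric, seq],
                             "p_value": self.p.loc[metric, seq],
                             "n": (self.n.loc[metric, seq]
                                   if self.n is not None else np.nan)})
        return pd.DataFrame(rows)


def significance_filter(report: AgreementReport,
                        alpha_level: float = 0.05) -> AgreementReport:
    """Mask correlations whose p-value fails the significance threshold.

    No multiplicity correction is applied; cells with ``p >= alpha_level``
    become NaN in the returned copy.
    """
    keep = report.p < alpha_level
    return AgreementReport(
        rho=report.rho.where(keep), p=report.p.where(keep),
        alpha=report.alpha.copy(),
        n=None if report.n is None else report.n.copy(),
        alpha_level_of_measurement=report.alpha_level_of_measurement,
        median_ranks=report.median_ranks.copy(),
    )


def median_rank(rho: pd.DataFrame) -> pd.Series:
    """Median across sequences of each metric's |rho| rank (1 = strongest).

    Within each sequence column, metrics are ranked by |rho| descending with
    average ranks for ties; all-missing columns are dropped.
    """
    absr = rho.abs()
    absr = absr.loc[:, absr.notna().any(axis=0)]
    if absr.shape[1] == 0:
        raise ValueError("no sequence with any defined correlation")
    ranks = absr.rank(axis=0, ascending=False, method="average")
    return ranks.median(axis=1)
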