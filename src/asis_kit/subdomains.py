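"""Subdomain panel analysis: can a few subdomains stand in for the full scale?

Exhaustive Spearman correlation scans of all 1-, 2- and 3-subsets of the
8 major subdomains against the total severity score, computed both with
the subset's own scores included in the total and with them removed (to
guard against the part-whole correlation artefact).  Also aggregates
questionnaire rankings of subdomain importance (rank sums placed in
ascending order) from parents, adult patients and clinicians.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .severity import (
    ALL_DOMAINS,
    MAJOR_DOMAINS,
    ConfigurationError,
    ValidationError,
    VisitRecord,
    total_severity,
)


class UndefinedCorrelationError(ValueError):
    """Spearman's rho is undefined when an input is constant."""


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's rank correlation (tie-aware, via average ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman_rho needs two equal-length samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant sample")
    return float(stats.spearmanr(x, y).statistic)


def spearman_pvalue(x: Sequence[float], y: Sequence[float]) -> float:
    """p-value for Spearman's rho via the t-approximation."""
    return float(stats.spearmanr(x, y).pvalue)


def _first_visit_frame(cohort: Sequence[VisitRecord]) -> pd.DataFrame:
    rows = []
    for v in cohort:
        row = {d: v.scores[d] for d in ALL_DOMAINS}
        row["total"] = total_severity(v)
        rows.append(row)
    return pd.DataFrame(rows)


def _safe_rho(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def subset_scan(cohort: Sequence[VisitRecord], m: int) -> pd.DataFrame:
    """Correlation of every m-subset of major subdomains with the total score.

    One visit per patient (the caller passes first visits).  For each of the
    C(8, m) subsets the subset-sum is correlated with the full total
    (``rho_included``) and with the total minus the subset's own scores
    (``rho_excluded``).  Rows where either variable is constant carry NaN.
    """
    if m not in (1, 2, 3):
        raise ConfigurationError(f"subset size m must be 1, 2 or 3, got {m}")
    if len(cohort) < 4:
        raise ValueError("subset scan needs >= 4 patients")
    df = _first_visit_frame(cohort)
    total = df["total"].to_numpy(dtype=float)
    rows = []
    for subset in combinations(MAJOR_DOMAINS, m):
        ssum = df[list(subset)].sum(axis=1).to_numpy(dtype=float)
        rows.append(
            {
                "subset": "+".join(subset),
                "m": m,
                "rho_included": _safe_rho(ssum, total),
                "rho_excluded": _safe_rho(ssum, total - ssum),
                "n": len(cohort),
            }
        )
    return pd.DataFrame(rows)


def panel_correlation(
    cohort: Sequence[VisitRecord], panel: Iterable[str], exclude: bool = False
) -> float:
    """Spearman rho between a panel-sum and the total severity score.

    With ``exclude=True`` the panel's own scores are removed from the total
    before correlating.  The panel may mix major and minor domains.
    """
    panel = list(panel)
    if not panel:
        raise ConfigurationError("panel must be a non-empty set of domains")
    unknown = set(panel) - set(ALL_DOMAINS)
    if unknown:
        raise ConfigurationError(f"unknown domain(s) in panel: {sorted(unknown)}")
    df = _first_visit_frame(cohort)
    psum = df[panel].sum(axis=1).to_numpy(dtype=float)
    total = df["total"].to_numpy(dtype=float)
    if exclude:
        total = total - psum
    return spearman_rho(psum, total)


def pairwise_domain_correlations(cohort: Sequence[VisitRecord]) -> pd.DataFrame:
    """Spearman correlation matrix between the 8 major subdomain scores."""
    df = _first_visit_frame(cohort)[list(MAJOR_DOMAINS)]
    mat = pd.DataFrame(
        np.eye(len(MAJOR_DOMAINS)), index=MAJOR_DOMAINS, columns=MAJOR_DOMAINS
    )
    for a, b in combinations(MAJOR_DOMAINS, 2):
        rho = _safe_rho(df[a].to_numpy(float), df[b].to_numpy(float))
        mat.loc[a, b] = mat.loc[b, a] = rho
    return mat


@dataclass
class RankTable:
    """Aggregated questionnaire ranking for one respondent group."""

    respondent_group: str
    rank_sums: dict[str, int]
    positions: dict[str, int]  # 1 = most important; dense ranking on ties


def aggregate_ranks(
    responses: pd.DataFrame, respondent_group: str = "parents"
) -> RankTable:
    """Sum per-respondent importance ranks and order items ascending.

    ``responses`` is respondent x item, each row a permutation-like ranking
    with values in 1..n_items (1 = most impact).  Items are ordered by
    ascending rank sum; tied sums share the lower position (dense ranking).
    """
    arr = responses.to_numpy()
    n_items = responses.shape[1]
    bad = (arr < 1) | (arr > n_items) | (arr != np.floor(arr))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValidationError(
            f"rank out of range 1..{n_items}: respondent {responses.index[r]!r}, "
            f"item {responses.columns[c]!r}, value {arr[r, c]!r}"
        )
    sums = responses.sum(axis=0)
    positions = stats.rankdata(sums.to_numpy(), method="dense").astype(int)
    return RankTable(
        respondent_group=respondent_group,
        rank_sums={item: int(s) for item, s in sums.items()},
        positions={item: int(p) for item, p in zip(sums.index, positions)},
    )
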