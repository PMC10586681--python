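"""Contingency and rank-based inference on module membership.

Chi-square tests of independence relate module membership to misuse
type (substance vs. behavior) and to problem intensity (low vs. high);
Kruskal-Wallis H tests compare per-participant emotion-label counts
across groups, with Dunn's z tests for pairwise follow-up.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import Corpus, PipelineConfig, ValidationError

__all__ = [
    "DegenerateTableError",
    "ContingencyResult",
    "RankTestResult",
    "chi_square_independence",
    "dichotomize_intensity",
    "kruskal_wallis",
    "dunn_pairwise",
    "misuse_by_module_table",
    "intensity_by_module_table",
    "emotion_group_tests",
]


class DegenerateTableError(ValueError):
    """A contingency table has a zero row or column margin."""


@dataclass
class ContingencyResult:
    observed: pd.DataFrame
    expected: pd.DataFrame
    chi2: float
    df: int
    n: int
    p_value: float
    residuals: pd.DataFrame  #: standardized Pearson residuals (O-E)/sqrt(E)

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "df": self.df,
            "n": self.n,
            "p_value": self.p_value,
            "observed": self.observed.to_dict(),
            "expected": self.expected.round(6).to_dict(),
            "residuals": self.residuals.round(6).to_dict(),
        }


def chi_square_independence(table) -> ContingencyResult:
    """Pearson chi-square test of independence, no continuity correction.

    Accepts a DataFrame or array of counts.  Standardized residuals
    (O-E)/sqrt(E) localize which cells drive a rejection.  A zero row or
    column margin makes the test degenerate.
    """
    df_in = table if isinstance(table, pd.DataFrame) else pd.DataFrame(np.asarray(table))
    obs = df_in.to_numpy(dtype=float)
    if obs.min() < 0:
        raise ValidationError("counts must be non-negative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise DegenerateTableError("zero margin in contingency table")
    chi2, p, dof, expected = stats.chi2_contingency(obs, correction=False)
    resid = (obs - expected) / np.sqrt(expected)
    return ContingencyResult(
        observed=df_in,
        expected=pd.DataFrame(expected, index=df_in.index, columns=df_in.columns),
        chi2=float(chi2),
        df=int(dof),
        n=int(obs.sum()),
        p_value=float(p),
        residuals=pd.DataFrame(resid, index=df_in.index, columns=df_in.columns),
    )


def dichotomize_intensity(records) -> dict[str, str]:
    """Split participants into intensity groups from the severity item.

    'Totally agree' (4) marks the high-intensity group; every other
    response (1-3) the low-intensity group.
    """
    return {
        rec.participant_id: "high" if rec.intensity_raw == 4 else "low"
        for rec in records
    }


@dataclass
class RankTestResult:
    h: float
    df: int
    p_value: float
    group_names: list[str]
    group_sizes: list[int]
    undefined: bool = False  #: all observations identical; H has no meaning
    dunn_z: pd.DataFrame | None = None
    dunn_p: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "H": self.h,
            "df": self.df,
            "p_value": self.p_value,
            "groups": self.group_names,
            "group_sizes": self.group_sizes,
            "undefined": self.undefined,
        }
        if self.dunn_z is not None:
            d["dunn_z"] = self.dunn_z.round(6).to_dict()
            d["dunn_p"] = self.dunn_p.round(6).to_dict()
        return d


def kruskal_wallis(groups: dict[str, list[float]] | list[list[float]]) -> RankTestResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square reference on k-1 df.

    When every observation across every group is identical the statistic
    is undefined (zero rank variance); the result is flagged rather than
    raised, because that situation occurs legitimately for rare labels.
    """
    if isinstance(groups, dict):
        names = list(groups)
        samples = [np.asarray(groups[g], dtype=float) for g in names]
    else:
        names = [str(i) for i in range(len(groups))]
        samples = [np.asarray(g, dtype=float) for g in groups]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValidationError("need >= 2 non-empty groups")
    sizes = [len(s) for s in samples]
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return RankTestResult(
            h=float("nan"),
            df=len(samples) - 1,
            p_value=float("nan"),
            group_names=names,
            group_sizes=sizes,
            undefined=True,
        )
    h, p = stats.kruskal(*samples)
    return RankTestResult(
        h=float(h),
        df=len(samples) - 1,
        p_value=float(p),
        group_names=names,
        group_sizes=sizes,
    )


def dunn_pairwise(
    groups: dict[str, list[float]] | list[list[float]],
    adjust: str = "none",
) -> RankTestResult:
    """Dunn's pairwise z tests on pooled ranks, with tie correction.

    For groups i, j the statistic is

        z = (rbar_i - rbar_j) / sqrt( (N(N+1)/12 - T) (1/n_i + 1/n_j) )

    with rbar the mean pooled mid-rank and T = sum(t^3 - t) / (12 (N-1))
    the tie correction.  Two-sided normal p-values, optionally Holm-
    adjusted (default: no adjustment).  Returns the omnibus result with
    the symmetric pairwise matrices attached (diagonal empty/NaN).
    """
    if adjust not in ("none", "holm"):
        raise ValidationError("adjust must be 'none' or 'holm'")
    omnibus = kruskal_wallis(groups)
    names = omnibus.group_names
    if isinstance(groups, dict):
        samples = [np.asarray(groups[g], dtype=float) for g in names]
    else:
        samples = [np.asarray(g, dtype=float) for g in groups]
    k = len(samples)
    z_mat = pd.DataFrame(np.nan, index=names, columns=names)
    p_mat = pd.DataFrame(np.nan, index=names, columns=names)

    pooled = np.concatenate(samples)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    bounds = np.cumsum([0] + [len(s) for s in samples])
    mean_ranks = [
        ranks[bounds[i] : bounds[i + 1]].mean() for i in range(k)
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(range(k), 2))
    zs, ps = [], []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / len(samples[i]) + 1.0 / len(samples[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        zs.append(z)
        ps.append(2.0 * stats.norm.sf(abs(z)))
    if adjust == "holm" and ps:
        ps = list(multipletests(ps, method="holm")[1])
    for (i, j), z, p in zip(pairs, zs, ps):
        z_mat.iloc[i, j] = z
        z_mat.iloc[j, i] = -z
        p_mat.iloc[i, j] = p_mat.iloc[j, i] = p
    omnibus.dunn_z = z_mat
    omnibus.dunn_p = p_mat
    return omnibus


# ---------------------------------------------------------------------------
# pipeline-level table builders


def _records_by_id(corpus: Corpus):
    return {r.participant_id: r for r in corpus.records}


def misuse_by_module_table(
    corpus: Corpus,
    assignments: dict[str, int | None],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Misuse kind (substance/behavior) by module membership counts."""
    recs = _records_by_id(corpus)
    counts: Counter = Counter()
    for pid, mod in assignments.items():
        if mod is None:
            continue
        kind = config.category_kinds.get(recs[pid].category)
        if kind in ("substance", "behavior"):
            counts[(kind, mod)] += 1
    modules = sorted({m for _, m in counts})
    table = pd.DataFrame(
        [[counts.get((kind, m), 0) for m in modules] for kind in ("substance", "behavior")],
        index=["substance", "behavior"],
        columns=modules,
    )
    return table


def intensity_by_module_table(
    corpus: Corpus,
    assignments: dict[str, int | None],
    config: PipelineConfig,
    kind: str | None = None,
) -> pd.DataFrame:
    """Intensity group (low/high) by module counts, optionally within
    substance users or behavior users only."""
    recs = _records_by_id(corpus)
    intensity = dichotomize_intensity(corpus.records)
    counts: Counter = Counter()
    for pid, mod in assignments.items():
        if mod is None:
            continue
        if kind is not None and config.category_kinds.get(recs[pid].category) != kind:
            continue
        counts[(intensity[pid], mod)] += 1
    modules = sorted({m for _, m in counts})
    return pd.DataFrame(
        [[counts.get((g, m), 0) for m in modules] for g in ("low", "high")],
        index=["low", "high"],
        columns=modules,
    )


def emotion_group_tests(
    corpus: Corpus,
    assignments: dict[str, int | None],
    retained_labels: list[str],
    config: PipelineConfig,
    grouping: str = "module",
) -> dict[str, RankTestResult]:
    """Kruskal-Wallis + Dunn tests per retained emotion label.

    The observation unit is the participant: for each label, the number
    of times the participant attached it to a retained association.
    ``grouping`` is "module" (groups = assigned modules) or "kind"
    (groups = substance vs. behavior users).
    """
    if grouping not in ("module", "kind"):
        raise ValidationError("grouping must be 'module' or 'kind'")
    recs = _records_by_id(corpus)
    results: dict[str, RankTestResult] = {}
    for label in retained_labels:
        groups: dict[str, list[float]] = {}
        for pid, mod in assignments.items():
            if mod is None:
                continue
            rec = recs[pid]
            if grouping == "module":
                key = f"module_{mod}"
            else:
                key = config.category_kinds.get(rec.category)
                if key not in ("substance", "behavior"):
                    continue
            count = sum(1 for pair in rec.emotion_labels for lab in pair if lab == label)
            groups.setdefault(key, []).append(float(count))
        if len(groups) < 2:
            continue
        ordered = {k: groups[k] for k in sorted(groups)}
        results[label] = dunn_pairwise(ordered, adjust=config.dunn_adjust)
    return results
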