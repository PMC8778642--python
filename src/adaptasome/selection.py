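"""Pairwise lifestyle contrasts and recurrence-based family selection.

The core procedure: for every pair of lifestyle groups, compute each protein
family's median copy number in both groups, test the distributional shift
with the two-sided Mann-Whitney-Wilcoxon rank-sum test, list the ten
families with the greatest absolute median difference (optionally gated on
significance), and finally select the families that recur in the top-ten
list of at least three contrasts — the candidate "adaptasome".

Normality is examined with a Shapiro-Wilk diagnostic, which motivates the
nonparametric test but never gates selection.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation_ingest import FamilyCountMatrix, FamilyKey
from .ecology import EcologyTable

__all__ = [
    "SelectionConfig",
    "PairContrast",
    "AdaptasomeSelection",
    "ShapiroResult",
    "group_medians",
    "mann_whitney",
    "shapiro_wilk_diagnostic",
    "compare_pair",
    "select_adaptasome",
    "run_selection",
]

logger = logging.getLogger("adaptasome.selection")

# auto mode switches to exact enumeration at or below this pooled size
EXACT_AUTO_LIMIT = 12


@dataclass(frozen=True)
class SelectionConfig:
    """Tunable knobs of the contrast-and-select procedure.

    ``correction`` defaults to per-contrast Benjamini-Hochberg: a screen of
    ~200 families over 45 overlapping contrasts produces, uncorrected, about
    ten nominally significant families per contrast under the null, and the
    recurrence rule then selects well over 5% of all families from noise
    alone.  Set ``correction=None`` to reproduce the uncorrected historical
    procedure.
    """

    alpha: float = 0.05
    max_k: int = 10
    min_recurrence: int = 3
    gate_by_significance: bool = True
    drop_shared: bool = False
    correction: str | None = "bh"  # "bh" (per contrast) or None (uncorrected)
    pairs: tuple[tuple[str, str], ...] | None = None  # None = all unordered pairs

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.max_k < 0:
            raise ValueError("max_k must be >= 0")
        if self.min_recurrence < 1:
            raise ValueError("min_recurrence must be >= 1")
        if self.correction not in (None, "bh"):
            raise ValueError(f"unknown correction {self.correction!r}")


# ---------------------------------------------------------------------------
# rank-sum machinery


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def _exact_two_sided_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Exact U and two-sided p over all C(n+m, n) group assignments.

    Uses a subset-sum dynamic programme over doubled midranks (doubling keeps
    tied half-ranks integral), so ties are handled by the true permutation
    distribution.  Under exchange of group labels the distribution of U is
    symmetric about nm/2; the two-sided p sums probability over assignments
    with |U - nm/2| at least as large as observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks2 = np.rint(2 * _midranks(pooled)).astype(np.int64)  # doubled midranks
    u_obs2 = int(ranks2[:n].sum()) - n * (n + 1)  # 2*U for x

    # dist[k] maps doubled rank-sum -> number of size-k subsets achieving it
    total = int(ranks2.sum())
    dist = np.zeros((n + 1, total + 1), dtype=np.float64)
    dist[0, 0] = 1.0
    for r in ranks2:
        for k in range(n, 0, -1):
            dist[k, r:] += dist[k - 1, : total + 1 - r]
    counts = dist[n]
    n_assign = counts.sum()

    center2 = n * m  # 2 * (nm / 2), on the doubled-U scale
    sums2 = np.arange(total + 1)
    u2 = sums2 - n * (n + 1)  # doubled U for each achievable rank-sum
    extreme = np.abs(u2 - center2) >= abs(u_obs2 - center2)
    p = counts[extreme].sum() / n_assign
    return u_obs2 / 2.0, min(1.0, float(p))


def mann_whitney(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney-Wilcoxon rank-sum test.

    Returns ``(U, p)`` with U the rank-sum statistic for ``x`` (midranks for
    ties).  The exact permutation p is used when ``mode='exact'`` or when
    ``mode='auto'`` with pooled size <= 12 and no ties; otherwise the normal
    approximation with tie and continuity correction (scipy).  If every
    pooled value is identical the test is degenerate and p = 1.
    """
    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return n * m / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "exact" or (mode == "auto" and n + m <= EXACT_AUTO_LIMIT and not has_ties):
        return _exact_two_sided_p(x, y)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def _mww_columns(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise MWW over two count blocks (organisms x families).

    Vectorizes the asymptotic test across families, then recomputes exactly
    the columns where the auto rule prefers enumeration, and fixes up the
    degenerate all-identical columns to p = 1.
    """
    n, m = a.shape[0], b.shape[0]
    nfam = a.shape[1]
    U = np.full(nfam, n * m / 2.0)
    p = np.ones(nfam)
    pooled = np.vstack([a, b])
    constant = np.all(pooled == pooled[0], axis=0)
    live = ~constant
    if live.any():
        with np.errstate(all="ignore"):
            res = stats.mannwhitneyu(
                a[:, live],
                b[:, live],
                alternative="two-sided",
                method="asymptotic",
                use_continuity=True,
                axis=0,
            )
        U[live] = res.statistic
        p[live] = np.minimum(1.0, res.pvalue)
    if n + m <= EXACT_AUTO_LIMIT:
        for j in np.nonzero(live)[0]:
            col = pooled[:, j]
            if np.unique(col).size == col.size:  # tie-free: auto goes exact
                U[j], p[j] = _exact_two_sided_p(a[:, j], b[:, j])
    return U, p


@dataclass(frozen=True)
class ShapiroResult:
    statistic: float
    p_value: float
    assessable: bool
    note: str = ""


def shapiro_wilk_diagnostic(values: Sequence[float]) -> ShapiroResult:
    """Shapiro-Wilk normality diagnostic (never gates selection).

    Samples smaller than 3 or with no variation are flagged "not assessable"
    rather than raising.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        return ShapiroResult(np.nan, np.nan, False, "n < 3: not assessable")
    if np.all(arr == arr[0]):
        return ShapiroResult(np.nan, np.nan, False, "constant sample: not assessable")
    if arr.size > 5000:
        return ShapiroResult(np.nan, np.nan, False, "n > 5000: not assessable")
    w, p = stats.shapiro(arr)
    return ShapiroResult(float(w), float(p), True)


# ---------------------------------------------------------------------------
# contrasts


def group_medians(
    matrix: FamilyCountMatrix, members: Sequence[str]
) -> pd.Series:
    """Per-family median copy number over ``members``.

    Even group sizes take the midpoint of the two central order statistics.
    Families unannotated in an organism count as 0, never missing.
    """
    if len(members) == 0:
        raise ValueError("member list must be nonempty")
    block = matrix.data.loc[list(members)]
    return block.median(axis=0)


@dataclass
class PairContrast:
    """One lifestyle-pair comparison across all families."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    table: pd.DataFrame  # index (database, family); columns median_a, median_b,
    # abs_median_diff, u_statistic, p_value, significant, top10

    @property
    def top10(self) -> list[FamilyKey]:
        return list(self.table.index[self.table["top10"]])

    def to_tsv(self, path_or_buf) -> None:
        out = self.table.reset_index()
        out = out[
            [
                "family",
                "database",
                "median_a",
                "median_b",
                "abs_median_diff",
                "u_statistic",
                "p_value",
                "significant",
                "top10",
            ]
        ]
        out.to_csv(path_or_buf, sep="\t", index=False)


def compare_pair(
    matrix: FamilyCountMatrix,
    ecology: EcologyTable,
    label_a: str,
    label_b: str,
    config: SelectionConfig = SelectionConfig(),
) -> PairContrast | None:
    """Contrast two lifestyle groups family by family.

    Returns ``None`` (with a logged warning) when either group is empty
    after the optional shared-organism drop.  The top-``max_k`` set ranks
    eligible families by absolute median difference; eligibility requires a
    nonzero difference and, when ``gate_by_significance``, a p-value below
    ``alpha`` (after the optional per-contrast Benjamini-Hochberg step).
    Ties at the cutoff break by smaller p, then family id.
    """
    members_a = [o for o in ecology.group_members(label_a) if o in set(matrix.organisms)]
    members_b = [o for o in ecology.group_members(label_b) if o in set(matrix.organisms)]
    if config.drop_shared:
        shared = set(members_a) & set(members_b)
        members_a = [o for o in members_a if o not in shared]
        members_b = [o for o in members_b if o not in shared]
    if not members_a or not members_b:
        logger.warning(
            "contrast %s vs %s skipped: empty group (n_a=%d, n_b=%d)",
            label_a,
            label_b,
            len(members_a),
            len(members_b),
        )
        return None

    a = matrix.data.loc[members_a].to_numpy(dtype=float)
    b = matrix.data.loc[members_b].to_numpy(dtype=float)
    med_a = np.median(a, axis=0)
    med_b = np.median(b, axis=0)
    diff = np.abs(med_a - med_b)
    U, p = _mww_columns(a, b)

    if config.correction == "bh" and len(p):
        significant = multipletests(p, alpha=config.alpha, method="fdr_bh")[0]
    else:
        significant = p < config.alpha

    families = matrix.families
    eligible = diff > 0
    if config.gate_by_significance:
        eligible &= significant
    order = sorted(
        np.nonzero(eligible)[0],
        key=lambda j: (-diff[j], p[j], families[j][1], families[j][0]),
    )
    top = set(order[: config.max_k])

    table = pd.DataFrame(
        {
            "median_a": med_a,
            "median_b": med_b,
            "abs_median_diff": diff,
            "u_statistic": U,
            "p_value": p,
            "significant": significant,
            "top10": [j in top for j in range(len(families))],
        },
        index=pd.MultiIndex.from_tuples(families, names=["database", "family"])
        if families
        else pd.MultiIndex.from_arrays([[], []], names=["database", "family"]),
    )
    logger.info(
        "contrast %s (n=%d) vs %s (n=%d): %d significant, %d top%d",
        label_a,
        len(members_a),
        label_b,
        len(members_b),
        int(np.asarray(significant).sum()),
        len(top),
        config.max_k,
    )
    return PairContrast(label_a, label_b, len(members_a), len(members_b), table)


# ---------------------------------------------------------------------------
# recurrence selection


@dataclass
class AdaptasomeSelection:
    """Recurrence counts across contrasts and the selected-family flags."""

    table: pd.DataFrame  # columns family, database, recurrence, selected
    min_recurrence: int

    @property
    def selected(self) -> list[FamilyKey]:
        sel = self.table[self.table["selected"]]
        return [(db, fam) for db, fam in zip(sel["database"], sel["family"])]

    def counts_by_database(self) -> dict[str, int]:
        sel = self.table[self.table["selected"]]
        return sel.groupby("database")["family"].nunique().to_dict()

    def to_tsv(self, path_or_buf) -> None:
        self.table.to_csv(path_or_buf, sep="\t", index=False)


def select_adaptasome(
    contrasts: Iterable[PairContrast],
    min_recurrence: int = 3,
    reference: pd.DataFrame | None = None,
) -> AdaptasomeSelection:
    """Select families recurring in the top-ten list of >= ``min_recurrence`` contrasts.

    ``reference`` optionally joins annotation columns (``predicted_name``,
    ``putative_role``) keyed on (family, database); it never affects which
    families are selected.
    """
    if min_recurrence < 1:
        raise ValueError("min_recurrence must be >= 1")
    recurrence: dict[FamilyKey, int] = {}
    for contrast in contrasts:
        for key in contrast.top10:
            recurrence[key] = recurrence.get(key, 0) + 1
    rows = sorted(recurrence.items(), key=lambda kv: (-kv[1], kv[0][1], kv[0][0]))
    table = pd.DataFrame(
        {
            "family": [fam for (_db, fam), _ in rows],
            "database": [db for (db, _fam), _ in rows],
            "recurrence": [r for _, r in rows],
        }
    )
    if table.empty:
        table = pd.DataFrame(columns=["family", "database", "recurrence"])
        table["recurrence"] = table["recurrence"].astype(int)
    table["selected"] = table["recurrence"] >= min_recurrence
    if reference is not None:
        ann = (
            reference.groupby(["family", "database"], sort=False)
            .agg(
                predicted_name=("predicted_name", lambda s: "; ".join(s)),
                putative_role=("putative_role", lambda s: "; ".join(dict.fromkeys(s))),
            )
            .reset_index()
        )
        table = table.merge(ann, on=["family", "database"], how="left")
    return AdaptasomeSelection(table=table, min_recurrence=min_recurrence)


def all_label_pairs(vocabulary: Iterable[str]) -> list[tuple[str, str]]:
    """All unordered label pairs, deterministically ordered."""
    return list(itertools.combinations(sorted(vocabulary), 2))


def run_selection(
    matrix: FamilyCountMatrix,
    ecology: EcologyTable,
    config: SelectionConfig = SelectionConfig(),
    reference: pd.DataFrame | None = None,
) -> tuple[list[PairContrast], AdaptasomeSelection, dict]:
    """Run every configured pairwise contrast and the recurrence selection.

    Returns the per-pair contrasts, the selection, and a summary dict with
    group sizes, skipped pairs and selected-family counts per source
    database.  Fully deterministic given inputs and config.
    """
    pairs = (
        list(config.pairs)
        if config.pairs is not None
        else all_label_pairs(ecology.vocabulary)
    )
    if not pairs:
        raise ValueError("no label pairs configured")
    for a, b in pairs:
        if a not in ecology.vocabulary or b not in ecology.vocabulary:
            raise ValueError(f"pair ({a!r}, {b!r}) uses labels outside the vocabulary")
    contrasts: list[PairContrast] = []
    skipped: list[tuple[str, str]] = []
    for a, b in pairs:
        contrast = compare_pair(matrix, ecology, a, b, config)
        if contrast is None:
            skipped.append((a, b))
        else:
            contrasts.append(contrast)
    selection = select_adaptasome(
        contrasts, min_recurrence=config.min_recurrence, reference=reference
    )
    summary = {
        "n_pairs_configured": len(pairs),
        "n_pairs_run": len(contrasts),
        "skipped_pairs": skipped,
        "group_sizes": {
            label: len(ecology.group_members(label)) for label in sorted(ecology.vocabulary)
        },
        "n_families_tested": len(matrix.families),
        "n_selected": int(selection.table["selected"].sum()),
        "selected_by_database": selection.counts_by_database(),
    }
    return contrasts, selection, summary
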