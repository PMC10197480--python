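"""Group contrasts of trait networks.

Records are split by life-form (woody vs herbaceous) or by aridity
region (aridity index below 0.2 → arid, at or above 0.2 → semi-arid;
the boundary itself goes to semi-arid by convention).  The full
network pipeline runs per group, and two tests mirror the standard
reporting style of trait-network studies:

* **Duncan's multiple range test** over the traits' bootstrap degree
  distributions (and over category importance), reported as letter
  groupings — items sharing a letter do not differ at the chosen
  level.  The step-down procedure uses studentized-range quantiles at
  the classical protection level ``1 - (1-alpha)**(span-1)``.
* **Welch's t-test** between the two groups' bootstrap distributions
  of edge density and modularity.  Bootstrap replicates are not
  independent samples, so these p-values are descriptive summaries of
  separation, not strict inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import ImportanceTable, NetworkMetrics, compute_metrics, importance
from .network import TraitNetwork, build_network
from .resampling import ResampleSummary, bootstrap_ptn
from .trait_data import TraitMatrix

logger = logging.getLogger(__name__)

ARIDITY_BOUNDARY = 0.2
#: Cap on the error degrees of freedom used when evaluating
#: studentized-range quantiles; beyond this the quantile is flat in df
#: to numerical precision and the evaluation is slow.
_MAX_RANGE_DF = 1000


# ---------------------------------------------------------------------------
# Group splitting


def split_groups(
    m: TraitMatrix,
    variable: str = "life_form",
    aridity_boundary: float = ARIDITY_BOUNDARY,
    min_records: int = 4,
) -> dict[str, TraitMatrix]:
    """Split records into disjoint groups by life-form or aridity region.

    Records with a missing group value are excluded (with a logged
    count).  A resulting group with fewer than ``min_records`` records
    raises, naming the group.
    """
    if variable == "life_form":
        if m.life_form is None:
            raise ValueError("trait matrix has no life_form labels")
        labels = [None if x is None else str(x) for x in m.life_form]
    elif variable == "aridity":
        if m.aridity_index is None:
            raise ValueError("trait matrix has no aridity_index values")
        labels = [
            None if not np.isfinite(ai)
            else ("arid" if ai < aridity_boundary else "semi-arid")
            for ai in m.aridity_index
        ]
    else:
        raise ValueError("variable must be 'life_form' or 'aridity'")

    groups: dict[str, list[int]] = {}
    excluded = 0
    for i, lab in enumerate(labels):
        if lab is None:
            excluded += 1
            continue
        groups.setdefault(lab, []).append(i)
    if excluded:
        logger.info("split_groups: %d records without a group value excluded",
                    excluded)
    out = {}
    for lab, idx in groups.items():
        if len(idx) < min_records:
            raise ValueError(
                f"group {lab!r} has only {len(idx)} records "
                f"(need >= {min_records} for correlations)"
            )
        out[lab] = m.subset(idx)
    return out


# ---------------------------------------------------------------------------
# Duncan's multiple range test


@dataclass
class DuncanResult:
    """Letter display of a step-down multiple range test."""

    items: list[str]          # sorted by mean, descending
    means: dict[str, float]
    letters: dict[str, str]
    alpha: float
    mse: float
    df: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item": self.items,
                "mean": [self.means[i] for i in self.items],
                "letters": [self.letters[i] for i in self.items],
            }
        )


@lru_cache(maxsize=4096)
def _range_quantile(span: int, df: int, alpha: float) -> float:
    """Studentized-range quantile at Duncan's protection level
    ``1 - (1-alpha)**(span-1)`` for ``span`` ordered means."""
    df = min(df, _MAX_RANGE_DF)
    return float(stats.studentized_range.ppf((1.0 - alpha) ** (span - 1), span, df))


def duncan_mrt(
    samples: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> DuncanResult:
    """Duncan's multiple range test with letter groupings.

    ``samples`` maps each item (for example, a trait) to its replicate
    vector.  Items are ranked by mean; the shortest significant range
    for a span of p means is ``q * sqrt(MSE / n_h)`` with the quantile
    from :func:`_range_quantile` and ``n_h`` the harmonic mean
    replicate count; ranges are tested step-down so that a range inside
    a non-significant one is never declared significant.  Letters are
    assigned from the highest mean (``a``) downward; zero pooled
    variance with unequal means yields all-distinct letters.
    """
    names = list(samples)
    if len(names) < 2:
        raise ValueError("need at least 2 items to compare")
    vecs = {k: np.asarray(samples[k], dtype=float) for k in names}
    for k, v in vecs.items():
        if v.size < 2:
            raise ValueError(f"item {k!r} needs at least 2 replicates")

    means = {k: float(v.mean()) for k, v in vecs.items()}
    ns = {k: v.size for k, v in vecs.items()}
    df = sum(n - 1 for n in ns.values())
    mse = sum((ns[k] - 1) * float(np.var(vecs[k], ddof=1)) for k in names) / df
    n_h = len(names) / sum(1.0 / n for n in ns.values())

    # sort descending by mean; ties by name for determinism
    order = sorted(names, key=lambda k: (-means[k], k))
    k = len(order)

    if mse == 0.0:
        logger.info("duncan_mrt: zero pooled variance; distinct means get "
                    "distinct letters")
        nonsig = np.zeros((k, k), dtype=bool)
        for i in range(k):
            for j in range(i, k):
                nonsig[i, j] = means[order[i]] == means[order[j]]
    else:
        sem = np.sqrt(mse / n_h)
        nonsig = np.zeros((k, k), dtype=bool)
        np.fill_diagonal(nonsig, True)
        # step-down: widest spans first; protection by containment
        for span in range(k, 1, -1):
            crit = _range_quantile(span, df, alpha) * sem
            for i in range(0, k - span + 1):
                j = i + span - 1
                contained = any(
                    nonsig[a, b]
                    for a in range(0, i + 1)
                    for b in range(j, k)
                    if (a, b) != (i, j) and b - a > j - i
                )
                if contained or (means[order[i]] - means[order[j]]) <= crit:
                    nonsig[i, j] = True

    letters = _letters_from_nonsig(order, nonsig)
    return DuncanResult(items=order, means=means, letters=letters,
                        alpha=alpha, mse=mse, df=df)


def _letters_from_nonsig(order: list[str], nonsig: np.ndarray) -> dict[str, str]:
    """Compact letter display from the non-significance matrix of the
    sorted means: each maximal non-significant run gets one letter."""
    k = len(order)
    intervals: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and nonsig[i, j + 1]:
            j += 1
        if not any(a <= i and j <= b for a, b in intervals):
            intervals.append((i, j))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    labels: dict[str, list[str]] = {name: [] for name in order}
    for lab_idx, (a, b) in enumerate(intervals):
        letter = alphabet[lab_idx % len(alphabet)] * (lab_idx // len(alphabet) + 1)
        for t in range(a, b + 1):
            labels[order[t]].append(letter)
    return {name: "".join(ls) for name, ls in labels.items()}


# ---------------------------------------------------------------------------
# Welch's t-test


@dataclass
class TTestResult:
    """Two-sided independent-samples t-test between replicate vectors."""

    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    kind: str = "welch"


def welch_ttest(
    a: Sequence[float], b: Sequence[float], pooled: bool = False
) -> TTestResult:
    """Welch's (default) or pooled-variance two-sided t-test.

    Both vectors constant and equal → t = 0, p = 1 by convention.
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.size < 2 or bv.size < 2:
        raise ValueError("each sample needs at least 2 values")
    va, vb = np.var(av, ddof=1), np.var(bv, ddof=1)
    if va == 0.0 and vb == 0.0:
        if av.mean() == bv.mean():
            logger.info("welch_ttest: both samples constant and equal; p = 1")
            return TTestResult(0.0, float(av.size + bv.size - 2), 1.0,
                               float(av.mean()), float(bv.mean()))
        return TTestResult(np.inf if av.mean() > bv.mean() else -np.inf,
                           float(av.size + bv.size - 2), 0.0,
                           float(av.mean()), float(bv.mean()))
    res = stats.ttest_ind(av, bv, equal_var=pooled)
    return TTestResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        mean_a=float(av.mean()),
        mean_b=float(bv.mean()),
        kind="pooled" if pooled else "welch",
    )


# ---------------------------------------------------------------------------
# Whole-pipeline group comparison


@dataclass
class GroupResult:
    """Everything the pipeline computes for a single group."""

    label: str
    n_records: int
    network: TraitNetwork
    metrics: NetworkMetrics
    importance: ImportanceTable | None
    bootstrap: dict[str, ResampleSummary]
    duncan_degree: DuncanResult | None = None
    duncan_importance: DuncanResult | None = None


@dataclass
class GroupComparisonReport:
    """Per-group results plus between-group tests on bootstrap
    distributions of edge density and modularity."""

    variable: str
    groups: dict[str, GroupResult]
    tests: dict[str, TTestResult] = field(default_factory=dict)
    test_pair: tuple[str, str] | None = None

    def tests_frame(self) -> pd.DataFrame:
        rows = []
        for param, t in self.tests.items():
            a, b = self.test_pair
            rows.append(
                {
                    "parameter": param,
                    "group_a": a,
                    "group_b": b,
                    "mean_a": t.mean_a,
                    "mean_b": t.mean_b,
                    "t": t.t,
                    "df": t.df,
                    "p": t.p,
                }
            )
        return pd.DataFrame(rows)


def compare_group_ptns(
    m: TraitMatrix,
    variable: str = "life_form",
    aridity_boundary: float = ARIDITY_BOUNDARY,
    B: int = 1000,
    fraction_min: float = 0.75,
    alpha: float = 0.05,
    seed: int = 0,
    method: str = "greedy",
) -> GroupComparisonReport:
    """Run the full network pipeline per group and compare the groups.

    Per group: trait network, metrics, category importance, and the
    species bootstrap of all parameters; within each group, Duncan's
    test over the traits' bootstrap degree vectors and over the
    bootstrap category-importance vectors.  Between the two groups (if
    exactly two): Welch's t on the bootstrap distributions of edge
    density and modularity.  With a single group, the report carries
    that group and no tests.
    """
    split = split_groups(m, variable=variable, aridity_boundary=aridity_boundary)
    labels = sorted(split)
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(len(labels))

    groups: dict[str, GroupResult] = {}
    for lab, sub_seed in zip(labels, streams):
        sub = split[lab]
        net = build_network(sub, alpha=alpha)
        met = compute_metrics(net, method=method,
                              seed=int(sub_seed.generate_state(1)[0] % (2**31)))
        imp = importance(met, sub.categories) if sub.categories else None
        boot = bootstrap_ptn(
            sub, B=B, fraction_min=fraction_min, alpha=alpha,
            seed=int(sub_seed.generate_state(1)[0] % (2**31)), method=method,
        )
        deg_samples = {
            t: boot[f"degree[{t}]"].replicates for t in sub.trait_names
        }
        dd = duncan_mrt(deg_samples, alpha=alpha)
        di = None
        if sub.categories:
            cat_samples = {}
            for cat in sub.categories:
                member_reps = np.vstack(
                    [boot[f"degree[{t}]"].replicates for t in cat.members]
                )
                cat_samples[cat.name] = member_reps.mean(axis=0)
            di = duncan_mrt(cat_samples, alpha=alpha)
        groups[lab] = GroupResult(
            label=lab,
            n_records=sub.n_records,
            network=net,
            metrics=met,
            importance=imp,
            bootstrap=boot,
            duncan_degree=dd,
            duncan_importance=di,
        )

    report = GroupComparisonReport(variable=variable, groups=groups)
    if len(labels) == 1:
        logger.warning("only one group present; no between-group tests")
        return report
    if len(labels) == 2:
        a, b = labels
        report.test_pair = (a, b)
        for param in ("edge_density", "modularity"):
            report.tests[param] = welch_ttest(
                groups[a].bootstrap[param].replicates,
                groups[b].bootstrap[param].replicates,
            )
    else:
        # pairwise tests for >2 groups, keyed "param|a|b"
        report.test_pair = None
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                for param in ("edge_density", "modularity"):
                    report.tests[f"{param}|{a}|{b}"] = welch_ttest(
                        groups[a].bootstrap[param].replicates,
                        groups[b].bootstrap[param].replicates,
                    )
    return report
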