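"""Resampling uncertainty for network parameters.

Two designs are supported.  The *species bootstrap* repeatedly draws a
random subset of the records (size uniform between three-quarters of
the data and all of it, without replacement), rebuilds the trait
network, and summarizes each parameter's distribution over replicates
with mean, SD, SE, minimum and maximum — SE being ``sd / sqrt(B)``.
The *rarefaction* (species-number) experiment draws a fixed number of
records per replicate — with replacement by default, duplicates kept as
rows — across an increasing ladder of counts, charting how edge density
and modularity depend on species richness.

Both operate on an already log-transformed matrix and are bit-
reproducible from their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import degree, detect_modules, edge_density
from .network import MIN_PAIR_N, TraitNetwork, _pearson_arrays
from .trait_data import TraitMatrix

logger = logging.getLogger(__name__)

DEFAULT_B = 5000
DEFAULT_FRACTION_MIN = 0.75
DEFAULT_R = 500
#: Fraction of failed replicate draws above which the input is treated
#: as degenerate and the run aborts.
MAX_RETRY_FRACTION = 0.01


@dataclass
class ResampleSummary:
    """Distribution summary of one network parameter over replicates."""

    parameter: str
    B: int
    mean: float
    sd: float
    se: float
    min: float
    max: float
    replicates: np.ndarray | None = None

    @classmethod
    def from_replicates(
        cls, parameter: str, values: np.ndarray, keep: bool = True
    ) -> "ResampleSummary":
        v = np.asarray(values, dtype=float)
        b = v.size
        # a constant replicate vector has sd exactly 0 (avoids float fuzz)
        sd = 0.0 if b == 1 or v.max() == v.min() else float(np.std(v, ddof=1))
        return cls(
            parameter=parameter,
            B=b,
            mean=float(np.mean(v)),
            sd=sd,
            se=sd / np.sqrt(b),
            min=float(np.min(v)),
            max=float(np.max(v)),
            replicates=v if keep else None,
        )

    def row(self) -> dict:
        return {
            "parameter": self.parameter,
            "mean": self.mean,
            "sd": self.sd,
            "se": self.se,
            "min": self.min,
            "max": self.max,
            "B": self.B,
        }


def summaries_frame(summaries: dict[str, ResampleSummary]) -> pd.DataFrame:
    """Tidy table, one row per parameter (mean/sd/se/min/max/B)."""
    return pd.DataFrame([s.row() for s in summaries.values()])


def _network_parameters(
    values: np.ndarray,
    trait_names: list[str],
    alpha: float,
    method: str,
    seed: int | None,
    min_n: int,
) -> tuple[float, float, np.ndarray]:
    """(edge_density, modularity, degree vector) of the thresholded
    network built from a raw value array.  Degenerate pairs (zero
    variance, too few complete records) simply contribute no edge."""
    _, pval, _ = _pearson_arrays(values, min_n=min_n)
    adj = (pval < alpha).astype(int)
    np.fill_diagonal(adj, 0)
    net = TraitNetwork(adjacency=adj, trait_names=trait_names, alpha=alpha)
    _, q = detect_modules(net, method=method, seed=seed)
    return edge_density(net), q, degree(net)


def bootstrap_ptn(
    m: TraitMatrix,
    B: int = DEFAULT_B,
    fraction_min: float = DEFAULT_FRACTION_MIN,
    alpha: float = 0.05,
    seed: int = 0,
    fixed_fraction: bool = False,
    method: str = "greedy",
    min_n: int = MIN_PAIR_N,
    keep_replicates: bool = True,
) -> dict[str, ResampleSummary]:
    """Species bootstrap of all network parameters.

    Each replicate samples, without replacement, a subset whose size is
    drawn uniformly from ``[ceil(fraction_min * n), n]`` (or exactly
    ``ceil(fraction_min * n)`` when ``fixed_fraction``), rebuilds the
    network at ``alpha``, and records edge density, modularity and every
    trait's degree.  Returns a summary per parameter, keyed
    ``edge_density``, ``modularity`` and ``degree[<trait>]``, each with
    ``se = sd / sqrt(B)``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not (0.0 < fraction_min <= 1.0):
        raise ValueError("fraction_min must be in (0, 1]")
    n = m.n_records
    lo = int(np.ceil(fraction_min * n))
    if lo < 4:
        raise ValueError(
            f"fraction_min * n = {lo} records is too few for correlations (need >= 4)"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    dens = np.empty(B)
    mods = np.empty(B)
    degs = np.empty((B, m.n_traits))
    retries = 0
    for b in range(B):
        while True:
            size = lo if fixed_fraction else int(rng.integers(lo, n + 1))
            idx = rng.choice(n, size=size, replace=False)
            if size >= 4:
                break
            retries += 1
            if retries > max(1, MAX_RETRY_FRACTION * B):
                raise RuntimeError("too many degenerate bootstrap replicates")
        louvain_seed = int(rng.integers(2**31 - 1)) if method == "louvain" else None
        dens[b], mods[b], degs[b] = _network_parameters(
            m.values[idx], m.trait_names, alpha, method, louvain_seed, min_n
        )
    if retries:
        logger.info("bootstrap retried %d degenerate draws", retries)

    out = {
        "edge_density": ResampleSummary.from_replicates(
            "edge_density", dens, keep_replicates
        ),
        "modularity": ResampleSummary.from_replicates(
            "modularity", mods, keep_replicates
        ),
    }
    for j, t in enumerate(m.trait_names):
        key = f"degree[{t}]"
        out[key] = ResampleSummary.from_replicates(key, degs[:, j], keep_replicates)
    return out


@dataclass
class RarefactionCurve:
    """Per-species-count parameter summaries from the rarefaction run."""

    species_counts: list[int]
    summaries: dict[int, dict[str, ResampleSummary]]
    replicates_per_count: int
    with_replacement: bool

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.species_counts:
            for s in self.summaries[c].values():
                rows.append({"species_count": c, **s.row()})
        return pd.DataFrame(rows)


def rarefaction(
    m: TraitMatrix,
    counts: list[int],
    R: int = DEFAULT_R,
    alpha: float = 0.05,
    seed: int = 0,
    with_replacement: bool = True,
    method: str = "greedy",
    min_n: int = MIN_PAIR_N,
    keep_replicates: bool = False,
) -> RarefactionCurve:
    """Species-number simulation: R networks per count of sampled records.

    ``with_replacement=True`` (the default) resamples records with
    replacement and keeps duplicates as rows; note that duplicate rows
    inflate the effective sample size behind each p-value, which is why
    a without-replacement mode is also offered (it then requires
    ``count <= n``).  Summarizes edge density and modularity per count.
    """
    counts = sorted(int(c) for c in counts)
    if len(counts) == 0:
        raise ValueError("counts must be non-empty")
    if counts[0] < 4:
        raise ValueError("every count must be >= 4 (correlation needs n-2 >= 2)")
    if len(set(counts)) != len(counts):
        raise ValueError("counts must be distinct")
    if R < 1:
        raise ValueError("R must be >= 1")
    n = m.n_records
    if not with_replacement and counts[-1] > n:
        raise ValueError(
            f"count {counts[-1]} exceeds the {n} available records "
            "(without replacement)"
        )
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(len(counts))
    summaries: dict[int, dict[str, ResampleSummary]] = {}
    for c, sub in zip(counts, streams):
        rng = np.random.default_rng(sub)
        dens = np.empty(R)
        mods = np.empty(R)
        for rep in range(R):
            idx = rng.choice(n, size=c, replace=with_replacement)
            louvain_seed = int(rng.integers(2**31 - 1)) if method == "louvain" else None
            dens[rep], mods[rep], _ = _network_parameters(
                m.values[idx], m.trait_names, alpha, method, louvain_seed, min_n
            )
        summaries[c] = {
            "edge_density": ResampleSummary.from_replicates(
                "edge_density", dens, keep_replicates
            ),
            "modularity": ResampleSummary.from_replicates(
                "modularity", mods, keep_replicates
            ),
        }
    return RarefactionCurve(
        species_counts=counts,
        summaries=summaries,
        replicates_per_count=R,
        with_replacement=with_replacement,
    )
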