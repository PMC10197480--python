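"""Synthetic trait matrices with planted correlation structure.

The field data behind dryland trait-network studies are rarely
deposited, so the pipeline ships a generator that emulates their
statistical shape: a few hundred species records, 16 strictly positive
traits with lognormal marginals, and a block-modular correlation
structure aligned with the functional categories — traits within a
category correlate at ``rho_in``, across categories at ``rho_out``
(``rho_out < rho_in``, so the planted modules are detectable in
expectation).  Records are drawn from a multivariate normal with that
correlation matrix on the log scale and exponentiated, which makes the
planted correlations exact on the scale where the pipeline computes
them (after its log-transform).

Optional extras mirror the study designs the pipeline targets: a
planted *hub* trait correlated with every other trait (default SPC, a
nod to stem phosphorus emerging as the hub in dryland floras), and
*groups* whose correlation strengths are scaled multiplicatively —
for example a "woody" group with weaker, more modular correlations
than an "herbaceous" one.  Group effects act on correlation strength,
not trait means, because the group contrasts of interest are about
connectivity.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .trait_data import DEFAULT_TRAITS, TraitMatrix, default_categories

logger = logging.getLogger(__name__)

#: Study-condition defaults: a ~188-record pool, intermediate
#: within-category correlation, weak between-category correlation.
DEFAULT_N_RECORDS = 188
DEFAULT_RHO_IN = 0.4
DEFAULT_RHO_OUT = 0.1
DEFAULT_LOG_SD = 0.5
#: AI range observed across temperate dryland sites.
ARIDITY_RANGE = (0.02, 0.51)
ARIDITY_BOUNDARY = 0.2


@dataclass(frozen=True)
class Block:
    """A planted module: label, member traits and within-module rho."""

    label: str
    members: tuple[str, ...]
    rho_in: float = DEFAULT_RHO_IN


@dataclass(frozen=True)
class SyntheticGroup:
    """A record group whose planted correlations are scaled by
    ``correlation_scale`` (applied to both rho_in and rho_out)."""

    label: str
    n_records: int
    correlation_scale: float = 1.0


def default_blocks(rho_in: float = DEFAULT_RHO_IN) -> tuple[Block, ...]:
    """Planted modules matching the functional categories (6/6/4)."""
    return tuple(Block(c.name, c.members, rho_in) for c in default_categories())


@dataclass
class SyntheticConfig:
    """Full description of a synthetic trait dataset.

    Parameters
    ----------
    n_records
        Rows to draw when ``groups`` is not given.
    blocks
        Planted modules with their within-module correlations.
    rho_out
        Between-module correlation; must be below every block's rho_in.
    log_mean, log_sd
        Marginal parameters on the log scale, shared or per trait.
    hub_trait, hub_rho
        Optional globally connected trait: its correlation with every
        trait outside its own block is raised to ``hub_rho``.
    groups
        Optional record groups with correlation-strength multipliers.
    group_variable
        Which metadata field the group labels populate: ``life_form``
        (labels woody/herbaceous) or ``aridity`` (labels arid/semi-arid,
        with aridity indices drawn on the matching side of 0.2).
    seed
        Master seed; every substream derives from it deterministically.
    """

    n_records: int = DEFAULT_N_RECORDS
    blocks: tuple[Block, ...] = field(default_factory=default_blocks)
    rho_out: float = DEFAULT_RHO_OUT
    log_mean: float | Mapping[str, float] = 0.0
    log_sd: float | Mapping[str, float] = DEFAULT_LOG_SD
    hub_trait: str | None = None
    hub_rho: float = 0.4
    groups: tuple[SyntheticGroup, ...] | None = None
    group_variable: str = "life_form"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.blocks, Sequence) and not isinstance(self.blocks, tuple):
            self.blocks = tuple(
                b if isinstance(b, Block) else Block(**b) for b in self.blocks
            )
        if self.groups is not None and not isinstance(self.groups, tuple):
            self.groups = tuple(
                g if isinstance(g, SyntheticGroup) else SyntheticGroup(**g)
                for g in self.groups
            )
        for b in self.blocks:
            if not (0.0 <= b.rho_in < 1.0):
                raise ValueError(f"block {b.label!r}: rho_in must be in [0, 1)")
            if self.rho_out >= b.rho_in and b.rho_in > 0:
                raise ValueError(
                    f"rho_out ({self.rho_out}) must be below block "
                    f"{b.label!r} rho_in ({b.rho_in})"
                )
        if self.rho_out < 0:
            raise ValueError("rho_out must be >= 0")
        if self.group_variable not in ("life_form", "aridity"):
            raise ValueError("group_variable must be 'life_form' or 'aridity'")

    @property
    def trait_names(self) -> list[str]:
        return [t for b in self.blocks for t in b.members]

    def planted_partition(self) -> dict[str, str]:
        """Ground-truth module label per trait."""
        return {t: b.label for b in self.blocks for t in b.members}

    def correlation_matrix(self, scale: float = 1.0) -> np.ndarray:
        """The implied (repaired-if-needed) trait correlation matrix."""
        names = self.trait_names
        p = len(names)
        idx = {t: i for i, t in enumerate(names)}
        r = np.full((p, p), self.rho_out * scale)
        for b in self.blocks:
            for a_t in b.members:
                for b_t in b.members:
                    r[idx[a_t], idx[b_t]] = b.rho_in * scale
        if self.hub_trait is not None:
            if self.hub_trait not in idx:
                raise ValueError(f"hub trait {self.hub_trait!r} not among traits")
            h = idx[self.hub_trait]
            hub_r = self.hub_rho * scale
            r[h, :] = np.maximum(r[h, :], hub_r)
            r[:, h] = np.maximum(r[:, h], hub_r)
        np.fill_diagonal(r, 1.0)
        return _ensure_psd(r)

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "n_records": self.n_records,
            "blocks": [
                {"label": b.label, "members": list(b.members), "rho_in": b.rho_in}
                for b in self.blocks
            ],
            "rho_out": self.rho_out,
            "log_mean": self.log_mean if np.isscalar(self.log_mean)
            else dict(self.log_mean),
            "log_sd": self.log_sd if np.isscalar(self.log_sd)
            else dict(self.log_sd),
            "hub_trait": self.hub_trait,
            "hub_rho": self.hub_rho,
            "group_variable": self.group_variable,
            "seed": self.seed,
        }
        if self.groups is not None:
            d["groups"] = [
                {
                    "label": g.label,
                    "n_records": g.n_records,
                    "correlation_scale": g.correlation_scale,
                }
                for g in self.groups
            ]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        if "blocks" in d:
            d["blocks"] = tuple(Block(m["label"], tuple(m["members"]),
                                      m.get("rho_in", DEFAULT_RHO_IN))
                                for m in d["blocks"])
        if d.get("groups") is not None:
            d["groups"] = tuple(SyntheticGroup(**g) for g in d["groups"])
        return cls(**d)


def _ensure_psd(r: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Return r, repaired to the nearest unit-diagonal PSD matrix if needed.

    Eigenvalue clipping with diagonal renormalization, iterated a few
    times (a light Higham-style projection).  Raises if the repair
    cannot reach PSD within tolerance.
    """
    out = (r + r.T) / 2.0
    for _ in range(100):
        w = np.linalg.eigvalsh(out)
        if w.min() >= -tol:
            return out
        if _ == 0:
            warnings.warn(
                "planted correlation matrix is not positive semi-definite; "
                "applying nearest-PSD repair",
                stacklevel=3,
            )
        w, v = np.linalg.eigh(out)
        out = (v * np.maximum(w, tol)) @ v.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        out = (out + out.T) / 2.0
    raise ValueError("correlation matrix could not be repaired to PSD")


def _marginal(par, names: list[str], default: float) -> np.ndarray:
    if np.isscalar(par):
        return np.full(len(names), float(par))
    return np.array([float(par.get(t, default)) for t in names])


def _draw(
    rng: np.random.Generator,
    n: int,
    corr: np.ndarray,
    mu: np.ndarray,
    sd: np.ndarray,
) -> np.ndarray:
    w, v = np.linalg.eigh(corr)
    root = v * np.sqrt(np.maximum(w, 0.0))
    z = rng.standard_normal((n, corr.shape[0]))
    return np.exp(mu + sd * (z @ root.T))


def generate(config: SyntheticConfig) -> TraitMatrix:
    """Draw a trait matrix with the configured planted structure.

    Fully reproducible from ``config.seed``; each group (or the single
    ungrouped pool) gets its own derived substream, so any one group
    can be regenerated in isolation.
    """
    names = config.trait_names
    mu = _marginal(config.log_mean, names, 0.0)
    sd = _marginal(config.log_sd, names, DEFAULT_LOG_SD)
    ss = np.random.SeedSequence(config.seed)

    cats = None
    if set(names) == set(DEFAULT_TRAITS):
        cats = default_categories()

    if config.groups is None:
        rng = np.random.default_rng(ss.spawn(1)[0])
        vals = _draw(rng, config.n_records, config.correlation_matrix(), mu, sd)
        ai = rng.uniform(*ARIDITY_RANGE, size=config.n_records)
        return TraitMatrix(
            values=vals,
            record_ids=[f"sp{i + 1:04d}" for i in range(config.n_records)],
            trait_names=names,
            categories=cats,
            aridity_index=ai,
        )

    streams = ss.spawn(len(config.groups))
    blocks_v, ids, lf, ai = [], [], [], []
    offset = 0
    for g, sub in zip(config.groups, streams):
        rng = np.random.default_rng(sub)
        corr = config.correlation_matrix(scale=g.correlation_scale)
        blocks_v.append(_draw(rng, g.n_records, corr, mu, sd))
        ids += [f"sp{offset + i + 1:04d}" for i in range(g.n_records)]
        offset += g.n_records
        if config.group_variable == "life_form":
            lf += [g.label] * g.n_records
            ai.append(rng.uniform(*ARIDITY_RANGE, size=g.n_records))
        else:
            lf += [None] * g.n_records
            lo, hi = ARIDITY_RANGE
            if g.label == "arid":
                ai.append(rng.uniform(lo, ARIDITY_BOUNDARY, size=g.n_records))
            elif g.label == "semi-arid":
                ai.append(rng.uniform(ARIDITY_BOUNDARY, hi, size=g.n_records))
            else:
                ai.append(rng.uniform(lo, hi, size=g.n_records))
    return TraitMatrix(
        values=np.vstack(blocks_v),
        record_ids=ids,
        trait_names=names,
        categories=cats,
        life_form=np.array(lf, dtype=object),
        aridity_index=np.concatenate(ai),
    )


def generate_null(
    n_records: int, p: int = 16, seed: int = 0
) -> TraitMatrix:
    """Mutually independent lognormal traits — the null against which the
    significance threshold is calibrated (expected edge density ≈ alpha)."""
    if n_records < 4:
        raise ValueError("need at least 4 records")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    vals = np.exp(rng.standard_normal((n_records, p)) * DEFAULT_LOG_SD)
    names = list(DEFAULT_TRAITS) if p == 16 else [f"T{i + 1:02d}" for i in range(p)]
    return TraitMatrix(
        values=vals,
        record_ids=[f"sp{i + 1:04d}" for i in range(n_records)],
        trait_names=names,
    )


def write_ground_truth(config: SyntheticConfig, path) -> None:
    """JSON sidecar with the planted partition and correlation matrix."""
    truth = {
        "planted_partition": config.planted_partition(),
        "trait_names": config.trait_names,
        "correlation_matrix": config.correlation_matrix().tolist(),
        "config": config.to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
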