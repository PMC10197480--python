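"""Trait-matrix data model and I/O.

The unit of analysis is a rectangular table of species records (rows)
by functional traits (columns).  Trait values are strictly positive
quantities (areas, concentrations, rates) and are log-transformed
before any correlation analysis; the network stages of this package
assume the transform has been applied.  Traits are partitioned into
three functional categories — economic, chemical and structural — used
later for the category-importance summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical trait order: six leaf economic traits, six stem/root
#: chemical traits, four leaf structural traits.
DEFAULT_TRAITS: tuple[str, ...] = (
    "A_area", "LMA", "LT", "LNC", "LCC", "LPC",
    "RCC", "RNC", "RPC", "SCC", "SNC", "SPC",
    "LD", "LV", "LDMC", "LA",
)


@dataclass(frozen=True)
class TraitCategory:
    """A named functional category and the traits that belong to it."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"category {self.name!r} lists a trait twice")


def default_categories() -> tuple[TraitCategory, ...]:
    """The default three-way functional partition of the 16 traits.

    Economic: photosynthesis and the leaf economics axis (A_area, LMA,
    LT, LNC, LCC, LPC).  Chemical: root and stem C/N/P concentrations
    (RCC, RNC, RPC, SCC, SNC, SPC).  Structural: leaf size, density and
    dry-matter traits (LD, LV, LDMC, LA).
    """
    return (
        TraitCategory("economic", ("A_area", "LMA", "LT", "LNC", "LCC", "LPC")),
        TraitCategory("chemical", ("RCC", "RNC", "RPC", "SCC", "SNC", "SPC")),
        TraitCategory("structural", ("LD", "LV", "LDMC", "LA")),
    )


def validate_categories(
    categories: Sequence[TraitCategory], trait_names: Sequence[str]
) -> None:
    """Check that ``categories`` form a disjoint cover of ``trait_names``."""
    seen: dict[str, str] = {}
    for cat in categories:
        for t in cat.members:
            if t in seen:
                raise ValueError(
                    f"trait {t!r} appears in categories {seen[t]!r} and {cat.name!r}"
                )
            seen[t] = cat.name
    missing = [t for t in trait_names if t not in seen]
    if missing:
        raise ValueError(f"traits without a category: {missing}")
    unknown = [t for t in seen if t not in trait_names]
    if unknown:
        raise ValueError(f"categories reference unknown traits: {unknown}")


@dataclass
class TraitMatrix:
    """Species-records × traits table with optional grouping metadata.

    Parameters
    ----------
    values
        ``(n, p)`` float array; ``NaN`` marks missing observations.
    record_ids
        ``n`` unique row identifiers (species or species-by-site codes).
    trait_names
        ``p`` unique trait column names.
    categories
        Functional partition of the traits; defaults to the standard
        economic/chemical/structural scheme when the traits match it.
    life_form
        Optional per-record growth-habit label (``"woody"`` or
        ``"herbaceous"``); ``None`` entries mean unknown.
    aridity_index
        Optional per-record aridity index (precipitation over potential
        evapotranspiration), a real in (0, 1); ``NaN`` means unknown.
    log_transformed
        Whether :func:`log_transform` has been applied.
    """

    values: np.ndarray
    record_ids: list[str]
    trait_names: list[str]
    categories: tuple[TraitCategory, ...] | None = None
    life_form: np.ndarray | None = None
    aridity_index: np.ndarray | None = None
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, p = self.values.shape
        self.record_ids = [str(r) for r in self.record_ids]
        self.trait_names = [str(t) for t in self.trait_names]
        if len(self.record_ids) != n:
            raise ValueError("record_ids length does not match values")
        if len(self.trait_names) != p:
            raise ValueError("trait_names length does not match values")
        dup = _duplicates(self.record_ids)
        if dup:
            raise ValueError(f"duplicate record ids: {sorted(dup)}")
        dup = _duplicates(self.trait_names)
        if dup:
            raise ValueError(f"duplicate trait names: {sorted(dup)}")
        if self.categories is None and set(self.trait_names) == set(DEFAULT_TRAITS):
            self.categories = default_categories()
        if self.categories is not None:
            validate_categories(self.categories, self.trait_names)
        if self.life_form is not None:
            self.life_form = np.asarray(self.life_form, dtype=object)
            if self.life_form.shape != (n,):
                raise ValueError("life_form must have one entry per record")
        if self.aridity_index is not None:
            self.aridity_index = np.asarray(self.aridity_index, dtype=float)
            if self.aridity_index.shape != (n,):
                raise ValueError("aridity_index must have one entry per record")

    # -- basic properties -------------------------------------------------

    @property
    def n_records(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, p)`` mask, True where the observation is missing."""
        return np.isnan(self.values)

    def category_of(self) -> dict[str, str]:
        """Map each trait to its category name (empty if no scheme)."""
        if self.categories is None:
            return {}
        return {t: c.name for c in self.categories for t in c.members}

    # -- derived matrices -------------------------------------------------

    def subset(self, indices: Sequence[int]) -> "TraitMatrix":
        """Row subset; repeated indices get ``#k`` suffixes to keep ids unique."""
        idx = np.asarray(indices, dtype=int)
        counts: dict[str, int] = {}
        ids = []
        for i in idx:
            rid = self.record_ids[i]
            k = counts.get(rid, 0)
            counts[rid] = k + 1
            ids.append(rid if k == 0 else f"{rid}#{k + 1}")
        return TraitMatrix(
            values=self.values[idx],
            record_ids=ids,
            trait_names=list(self.trait_names),
            categories=self.categories,
            life_form=None if self.life_form is None else self.life_form[idx],
            aridity_index=None
            if self.aridity_index is None
            else self.aridity_index[idx],
            log_transformed=self.log_transformed,
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: id index, trait columns, group columns appended."""
        df = pd.DataFrame(
            self.values, index=pd.Index(self.record_ids, name="record_id"),
            columns=self.trait_names,
        )
        if self.life_form is not None:
            df["life_form"] = self.life_form
        if self.aridity_index is not None:
            df["aridity_index"] = self.aridity_index
        return df


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        (dup if x in seen else seen).add(x)
    return dup


# ---------------------------------------------------------------------------
# I/O


def read_trait_table(
    path,
    schema: Mapping[str, object] | None = None,
    sep: str | None = None,
) -> TraitMatrix:
    """Read a delimited trait table into a :class:`TraitMatrix`.

    Parameters
    ----------
    path
        CSV/TSV file with a header row.
    schema
        Column-role mapping with keys ``id``, ``traits`` (list of trait
        column names) and optionally ``life_form`` and ``aridity_index``.
        When omitted, the ``record_id`` column and the 16 default trait
        names are assumed, with ``life_form``/``aridity_index`` picked up
        if present.
    sep
        Field delimiter; inferred from the filename when ``None``
        (``.tsv`` → tab, otherwise comma).

    Unparseable numeric cells (for example ``"NA"``) become missing
    values.  Row order is preserved.  Raises ``ValueError`` for
    duplicate ids, absent trait columns, and non-positive trait values
    (the log-transform would be undefined).
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if schema is None:
        schema = {}
    id_col = str(schema.get("id", "record_id"))
    traits = [str(t) for t in schema.get("traits", DEFAULT_TRAITS)]
    lf_col = schema.get("life_form", "life_form" if "life_form" in df.columns else None)
    ai_col = schema.get(
        "aridity_index", "aridity_index" if "aridity_index" in df.columns else None
    )

    if id_col not in df.columns:
        raise ValueError(f"id column {id_col!r} not found in {path}")
    missing_cols = [t for t in traits if t not in df.columns]
    if missing_cols:
        raise ValueError(f"trait columns missing from {path}: {missing_cols}")

    ids = df[id_col].astype(str).tolist()
    values = np.column_stack(
        [pd.to_numeric(df[t], errors="coerce").to_numpy(dtype=float) for t in traits]
    )
    bad = np.argwhere(~np.isnan(values) & (values <= 0))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive value {values[i, j]!r} at record {ids[i]!r}, "
            f"trait {traits[j]!r}: log-transform undefined"
        )

    life_form = None
    if lf_col is not None:
        lf = df[str(lf_col)].where(df[str(lf_col)].notna(), None)
        life_form = lf.to_numpy(dtype=object)
    aridity = None
    if ai_col is not None:
        aridity = pd.to_numeric(df[str(ai_col)], errors="coerce").to_numpy(dtype=float)

    return TraitMatrix(
        values=values,
        record_ids=ids,
        trait_names=traits,
        life_form=life_form,
        aridity_index=aridity,
    )


def write_trait_table(m: TraitMatrix, path) -> None:
    """Write the canonical wide CSV form of a trait matrix."""
    m.to_frame().to_csv(path)


# ---------------------------------------------------------------------------
# Transforms


def log_transform(m: TraitMatrix) -> TraitMatrix:
    """Natural-log transform every observed trait value.

    Correlations (and hence every network quantity downstream) are
    invariant to the base of the logarithm, so natural log is used.
    Missing entries stay missing; metadata is unchanged.  Raises
    ``ValueError`` if any observed value is non-positive.
    """
    obs = ~np.isnan(m.values)
    if np.any(m.values[obs] <= 0):
        i, j = np.argwhere(obs & (m.values <= 0))[0]
        raise ValueError(
            f"non-positive value at record {m.record_ids[i]!r}, "
            f"trait {m.trait_names[j]!r}: cannot log-transform"
        )
    out = np.full_like(m.values, np.nan)
    out[obs] = np.log(m.values[obs])
    return replace(m, values=out, log_transformed=True)


def aggregate_records(m: TraitMatrix, by: Sequence[str]) -> TraitMatrix:
    """Average records into aggregation units (for example, species means).

    ``by`` assigns each record an aggregation-unit label; the output has
    one row per unit in order of first appearance, each trait being the
    arithmetic mean of the unit's observed values (all-missing → missing).
    Aggregation happens on the raw scale; the pipeline default is to
    aggregate first and log-transform after, and the two orders do not
    commute.  Group labels are carried over when constant within a unit.
    """
    labels = list(by)
    if len(labels) == 0 or len(labels) != m.n_records:
        raise ValueError("grouping must assign one label per record")
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, lab in enumerate(str(x) for x in labels):
        if lab not in groups:
            groups[lab] = []
            order.append(lab)
        groups[lab].append(i)

    vals = np.full((len(order), m.n_traits), np.nan)
    lf: list[object] = []
    ai: list[float] = []
    for u, lab in enumerate(order):
        idx = groups[lab]
        block = m.values[idx]
        cnt = np.sum(~np.isnan(block), axis=0)
        tot = np.nansum(np.where(np.isnan(block), 0.0, block), axis=0)
        vals[u] = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
        if m.life_form is not None:
            uniq = {x for x in m.life_form[idx] if x is not None}
            lf.append(uniq.pop() if len(uniq) == 1 else None)
        if m.aridity_index is not None:
            ai.append(float(np.nanmean(m.aridity_index[idx])))
    return TraitMatrix(
        values=vals,
        record_ids=order,
        trait_names=list(m.trait_names),
        categories=m.categories,
        life_form=np.array(lf, dtype=object) if m.life_form is not None else None,
        aridity_index=np.array(ai) if m.aridity_index is not None else None,
        log_transformed=m.log_transformed,
    )
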