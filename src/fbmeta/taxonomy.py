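"""Best-hit taxonomic assignment and rank-level abundance aggregation.

Each gene receives the lineage of its highest-bitscore database hit; TPM is
then summed per taxon at a requested rank (family or higher).  Taxa below a
relative-abundance threshold can be pooled into a ``"Below 1%"`` category.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import BlastHit

logger = logging.getLogger(__name__)

#: Ordered taxonomic ranks carried by :class:`Lineage`, highest first.
RANKS = ("superkingdom", "phylum", "class_", "order", "family", "genus")

#: Rank labels as used in external interfaces (no trailing underscore).
RANK_NAMES = ("superkingdom", "phylum", "class", "order", "family", "genus")

#: Labels reserved for pseudo-categories; never valid taxon names.
RESERVED_LABELS = frozenset({"unassigned", "Below 1%"})

#: Label used for genes with no taxonomic hit.
UNASSIGNED = "unassigned"

BELOW_LABEL = "Below 1%"


@dataclass(frozen=True)
class Lineage:
    """A gapless rank path from superkingdom downwards.

    Any *suffix* of ranks may be absent (``None``), but a present rank
    implies every higher rank is present too.
    """

    superkingdom: str | None = None
    phylum: str | None = None
    class_: str | None = None
    order: str | None = None
    family: str | None = None
    genus: str | None = None

    def __post_init__(self) -> None:
        seen_gap = False
        for rank in RANKS:
            value = getattr(self, rank)
            if value is None:
                seen_gap = True
            else:
                if seen_gap:
                    raise ValueError(
                        f"lineage has a gap: {rank}={value!r} but a higher rank is absent"
                    )
                if value in RESERVED_LABELS:
                    raise ValueError(f"reserved label {value!r} used as a taxon name")

    @classmethod
    def from_string(cls, text: str) -> "Lineage":
        """Parse a semicolon-joined rank path, e.g. ``"Bacteria;Proteobacteria"``."""
        parts = [p.strip() for p in text.split(";") if p.strip()]
        if len(parts) > len(RANKS):
            raise ValueError(f"lineage has more than {len(RANKS)} ranks: {text!r}")
        return cls(**dict(zip(RANKS, parts)))

    def to_string(self) -> str:
        return ";".join(v for v in self.values if v is not None)

    @property
    def values(self) -> tuple[str | None, ...]:
        return tuple(getattr(self, rank) for rank in RANKS)

    def at_rank(self, rank: str) -> str | None:
        """Value at ``rank`` (external name, e.g. ``"class"``), or None."""
        return getattr(self, _internal_rank(rank))

    def label_at_rank(self, rank: str) -> str:
        """Taxon label at ``rank`` with unclassified roll-up.

        Genes whose lineage stops above ``rank`` roll up to
        ``"unclassified <nearest present higher rank>"``; an entirely empty
        lineage yields :data:`UNASSIGNED`.
        """
        value = self.at_rank(rank)
        if value is not None:
            return value
        nearest = None
        for r in RANKS:
            v = getattr(self, r)
            if v is None:
                break
            nearest = v
        if nearest is None:
            return UNASSIGNED
        return f"unclassified {nearest}"

    def matches(self, focal: str) -> bool:
        """True if every ``:``-separated token of ``focal`` is a rank value."""
        tokens = [t for t in focal.split(":") if t]
        present = {v for v in self.values if v is not None}
        return bool(tokens) and all(t in present for t in tokens)


def _internal_rank(rank: str) -> str:
    if rank == "class":
        return "class_"
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    return rank


def assign_best_hit(
    hits: Iterable[BlastHit],
    taxmap: Mapping[str, Lineage],
) -> dict[str, Lineage]:
    """Assign each query gene the lineage of its best hit.

    The best hit has the maximal bitscore; ties are broken by lower evalue,
    then by lexicographically smaller subject id.  Subjects missing from
    ``taxmap`` map to an empty (unassigned) lineage with a warning.
    """
    best: dict[str, BlastHit] = {}
    for hit in hits:
        incumbent = best.get(hit.query_id)
        if incumbent is None or _hit_key(hit) < _hit_key(incumbent):
            best[hit.query_id] = hit
    out: dict[str, Lineage] = {}
    for gene, hit in best.items():
        lineage = taxmap.get(hit.subject_id)
        if lineage is None:
            logger.warning("subject %s not in taxmap; gene %s unassigned", hit.subject_id, gene)
            lineage = Lineage()
        out[gene] = lineage
    return out


def _hit_key(hit: BlastHit) -> tuple:
    # sort ascending: highest bitscore, then lowest evalue, then subject id
    return (-hit.bitscore, hit.evalue, hit.subject_id)


def aggregate_by_rank(
    tpm: "pd.DataFrame | object",
    lineages: Mapping[str, Lineage],
    rank: str = "family",
) -> pd.DataFrame:
    """Sum TPM per taxon at ``rank`` (samples x taxa wide table).

    ``rank`` must be family or higher — the reporting floor.  Genes without
    a lineage fall into :data:`UNASSIGNED`; lineages stopping above the rank
    roll up to ``"unclassified <higher taxon>"``.  Mass is conserved.
    """
    if rank == "genus":
        raise ValueError("ranks below family are not reported")
    _internal_rank(rank)  # validates
    data = getattr(tpm, "data", tpm)
    labels = [
        lineages.get(g, Lineage()).label_at_rank(rank) if g in lineages else UNASSIGNED
        for g in data.columns
    ]
    profile = data.T.groupby(pd.Index(labels, name=rank)).sum().T
    profile.index.name = data.index.name or "sample"
    return profile


def group_below_threshold(profile: pd.DataFrame, threshold: float = 0.01) -> pd.DataFrame:
    """Merge taxa below ``threshold`` of total profile mass into ``"Below 1%"``.

    The share is computed over the whole profile (all samples, all
    categories including unassigned).  Mass is conserved exactly.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    total = float(profile.to_numpy().sum())
    if total == 0:
        return profile.copy()
    shares = profile.sum(axis=0) / total
    minor = shares.index[shares < threshold]
    if len(minor) == 0:
        return profile.copy()
    kept = profile.drop(columns=minor)
    kept[BELOW_LABEL] = profile[minor].sum(axis=1)
    return kept


def family_richness(
    tpm: "pd.DataFrame | object",
    lineages: Mapping[str, Lineage],
    groups: Mapping[str, str] | None = None,
) -> tuple[pd.Series, pd.Series | None]:
    """Count distinct real families per sample among genes with TPM > 0.

    Pseudo-labels (unassigned, unclassified roll-ups) are excluded.  If
    ``groups`` maps sample -> group label, the per-group median (standard
    midpoint rule) is returned as a second series.
    """
    data = getattr(tpm, "data", tpm)
    fam = np.array(
        [
            (lineages[g].family if g in lineages and lineages[g].family is not None else None)
            for g in data.columns
        ],
        dtype=object,
    )
    counts = {}
    present = data.to_numpy() > 0
    for i, sample in enumerate(data.index):
        counts[sample] = len({f for f in fam[present[i]] if f is not None})
    richness = pd.Series(counts, name="n_families")
    medians = None
    if groups is not None:
        medians = richness.groupby(pd.Series(groups)).median()
    return richness, medians


def focal_share(
    tpm: "pd.DataFrame | object",
    lineages: Mapping[str, Lineage],
    focal: str,
) -> pd.Series:
    """Fraction of each sample's TPM carried by genes matching ``focal``."""
    data = getattr(tpm, "data", tpm)
    mask = np.array([g in lineages and lineages[g].matches(focal) for g in data.columns])
    if not mask.any():
        raise ValueError(f"focal taxon {focal!r} not found in any lineage")
    totals = data.sum(axis=1)
    with np.errstate(invalid="ignore"):
        share = data.loc[:, mask].sum(axis=1) / totals
    return share.fillna(0.0)
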