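"""Taxon-resolved CAZyme substrate profiling.

CAZy family labels are mapped to substrate targets through an editable TSV
resource, TPM is split between the focal organism and everything else, and
aggregated by taxon group and target.  A gene carrying families with
several distinct targets has its TPM divided equally among them, so mass
is conserved exactly.
"""
from __future__ import annotations

import hashlib
import logging
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quantify import TpmMatrix
from .taxonomy import BELOW_LABEL, Lineage, UNASSIGNED

logger = logging.getLogger(__name__)

UNKNOWN_TARGET = "unknown"

_PROFILE_COLUMNS = ["sample", "origin", "taxon", "target", "tpm"]


def default_substrate_map_path() -> Path:
    return Path(str(resources.files("fbmeta").joinpath("data/substrate_map.tsv")))


def load_substrate_map(path: str | Path | None = None) -> dict[str, str]:
    """Load the CAZy family -> substrate target table and log its checksum."""
    p = Path(path) if path is not None else default_substrate_map_path()
    digest = hashlib.sha256(p.read_bytes()).hexdigest()
    logger.info("substrate map %s sha256=%s", p, digest)
    df = pd.read_csv(p, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["cazy_family", "target"]:
        raise ValueError(f"{p}: expected columns cazy_family, target")
    return dict(zip(df.cazy_family, df.target))


def map_substrates(families: Sequence[str], smap: Mapping[str, str]) -> set[str]:
    """Distinct substrate targets of a gene's CAZy families.

    Subfamily suffixes (``GH5_5``) fall back to the base family; families
    absent from the map resolve to ``"unknown"``.
    """
    targets = set()
    for fam in families:
        target = smap.get(fam)
        if target is None and "_" in fam:
            target = smap.get(fam.split("_", 1)[0])
        targets.add(target if target is not None else UNKNOWN_TARGET)
    return targets


def build_profile(
    tpm: TpmMatrix | pd.DataFrame,
    gene_families: Mapping[str, Sequence[str]],
    lineages: Mapping[str, Lineage],
    focal_taxon: str,
    smap: Mapping[str, str],
    rank: str = "phylum",
) -> pd.DataFrame:
    """Long-format (sample, origin, taxon, target, tpm) CAZyme profile.

    Restricted to genes with at least one CAZy family.  ``origin`` is
    ``focal`` when the best-hit lineage matches ``focal_taxon``, else
    ``non-focal``.  Taxon labels are taken at ``rank`` with unclassified
    roll-up.  Per-sample mass equals the sample's total CAZyme-gene TPM.
    """
    if rank not in ("superkingdom", "phylum", "family"):
        raise ValueError(f"unsupported rank {rank!r}")
    data = getattr(tpm, "data", tpm)
    caz_genes = [g for g in data.columns if gene_families.get(g)]
    if not any(
        g in lineages and lineages[g].matches(focal_taxon) for g in data.columns
    ):
        raise ValueError(f"focal taxon {focal_taxon!r} not resolvable in lineages")

    rows = []
    for g in caz_genes:
        lineage = lineages.get(g, Lineage())
        origin = "focal" if lineage.matches(focal_taxon) else "non-focal"
        taxon = lineage.label_at_rank(rank) if lineage.values[0] is not None else UNASSIGNED
        targets = sorted(map_substrates(gene_families[g], smap))
        w = 1.0 / len(targets)
        col = data[g]
        for sample, value in col.items():
            if value > 0:
                for target in targets:
                    rows.append((sample, origin, taxon, target, value * w))
    profile = pd.DataFrame(rows, columns=_PROFILE_COLUMNS)
    if profile.empty:
        return profile
    return (
        profile.groupby(["sample", "origin", "taxon", "target"], as_index=False)["tpm"]
        .sum()
        .sort_values(_PROFILE_COLUMNS[:4], ignore_index=True)
    )


def group_targets_below(profile: pd.DataFrame, threshold: float = 0.01) -> pd.DataFrame:
    """Pool targets below ``threshold`` of total profile TPM into ``"Below 1%"``.

    Mass is conserved exactly.
    """
    if profile.empty:
        return profile.copy()
    total = profile["tpm"].sum()
    if total == 0:
        return profile.copy()
    by_target = profile.groupby("target")["tpm"].sum()
    minor = set(by_target.index[(by_target / total) < threshold])
    if not minor:
        return profile.copy()
    out = profile.copy()
    out.loc[out["target"].isin(minor), "target"] = BELOW_LABEL
    return (
        out.groupby(["sample", "origin", "taxon", "target"], as_index=False)["tpm"]
        .sum()
        .sort_values(_PROFILE_COLUMNS[:4], ignore_index=True)
    )


def target_share_table(profile: pd.DataFrame) -> pd.DataFrame:
    """Add per-sample shares (cell / sample total CAZyme TPM).

    Shares are normalized over CAZyme TPM only, not total sample TPM; rows
    of a sample sum to 1.  Samples with zero CAZyme TPM get empty rows and
    a warning.
    """
    if profile.empty:
        raise ValueError("profile is empty")
    totals = profile.groupby("sample")["tpm"].transform("sum")
    zero = totals == 0
    if zero.any():
        for s in profile.loc[zero, "sample"].unique():
            logger.warning("sample %s has zero CAZyme TPM; shares dropped", s)
    out = profile.loc[~zero].copy()
    out["share"] = out["tpm"] / totals[~zero]
    return out
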