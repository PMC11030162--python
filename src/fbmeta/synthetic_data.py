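"""Synthetic annotated microbial communities with planted ground truth.

Generates gene annotation tables, metagenome/metatranscriptome count
matrices and the matching truth record for a two-condition community:
healthy samples dominated by one focal fungal taxon, rotten samples
dominated by diverse bacterial families, with planted KEGG modules and
CAZyme genes whose recovery downstream stages are tested against.

Counts are Dirichlet-multinomial: per-sample family shares are drawn
around the spec shares with configurable overdispersion, gene shares
within a family are proportional to length x a fixed within-family
weight, and reads are multinomial at the stated depth (so per-sample
totals equal the depth exactly).  Identical (spec, seed) pairs produce
byte-identical outputs.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .io_formats import BlastHit, DbcanRow, KofamRow, ModuleFlatRecord
from .kegg_modules import NITROGENASE_KOS, parse_definition, required_kos
from .quantify import CountMatrix
from .taxonomy import Lineage

HEALTHY = "healthy"
ROTTEN = "rotten"
TRANSITIONAL = "transitional"

#: Label for the pool of genes with no taxonomic assignment.
UNASSIGNED_POOL = "unassigned_pool"


def default_modules_path() -> Path:
    return Path(str(resources.files("fbmeta").joinpath("data/modules.flat")))


def load_default_modules() -> list[ModuleFlatRecord]:
    return io_formats.read_module_flatfile(default_modules_path())


def load_default_repertoire() -> list[str]:
    path = Path(str(resources.files("fbmeta").joinpath("data/ko_repertoire.tsv")))
    df = pd.read_csv(path, sep="\t", dtype=str)
    return list(df.ko_id)


@dataclass(frozen=True)
class FamilySpec:
    """One community member family and its share weights per condition."""

    label: str
    lineage: Lineage | None  # None marks the unassigned gene pool
    kind: str  # focal | bacterial | eukaryote | arthropod | unassigned
    healthy_weight: float
    rotten_weight: float


@dataclass(frozen=True)
class PlantedCazyme:
    """CAZyme genes planted in one family; multi-family tuples share a gene."""

    family: str
    cazy_families: tuple[str, ...]
    n_genes: int
    mt_boost: bool = False  # concentrated in rotten metatranscriptomes


@dataclass
class CommunitySpec:
    """Parameters of the synthetic community."""

    families: tuple[FamilySpec, ...]
    focal_taxon: str = "Fomes"
    healthy_focal_share: float = 0.80
    rotten_focal_share: float = 0.001
    genes_per_family: int = 40
    depth: int = 100_000
    overdispersion: float = 0.002
    planted_modules: dict[str, tuple[str, ...]] = field(default_factory=dict)
    planted_kos: dict[str, tuple[str, ...]] = field(default_factory=dict)
    omit_kos: frozenset[str] = frozenset(NITROGENASE_KOS)
    planted_cazymes: tuple[PlantedCazyme, ...] = ()
    # Free choice: the study reports only that most rotten transcription was
    # unassignable; 0.5 is the default fraction of rotten MT mass placed on
    # unassigned genes.
    unassigned_mt_fraction: float = 0.5
    cazyme_mt_boost: float = 0.20

    def __post_init__(self) -> None:
        for share in (self.healthy_focal_share, self.rotten_focal_share):
            if not 0 <= share <= 1:
                raise ValueError("focal shares must lie in [0, 1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be nonnegative")
        labels = [f.label for f in self.families]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate family labels")
        if not any(f.kind == "focal" for f in self.families):
            raise ValueError("spec needs exactly one focal family")
        known = set(labels)
        for source in (self.planted_modules, self.planted_kos):
            for fam in source:
                if fam not in known:
                    raise ValueError(f"planted family {fam!r} not in community")
        for pc in self.planted_cazymes:
            if pc.family not in known:
                raise ValueError(f"planted CAZyme family {pc.family!r} not in community")

    @property
    def focal_family(self) -> FamilySpec:
        return next(f for f in self.families if f.kind == "focal")


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    labels: dict[str, str]  # sample -> condition
    family_shares: pd.DataFrame  # samples x family labels (expected shares)
    planted_modules: dict[str, tuple[str, ...]]
    planted_cazymes: tuple[PlantedCazyme, ...]

    def __post_init__(self) -> None:
        sums = self.family_shares.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("family shares must sum to 1 per sample")


@dataclass
class SyntheticBundle:
    """Everything `generate` produces, ready to analyse or write out."""

    genes: pd.DataFrame  # gene_id, family, lineage, length_bp, ko_id, cazy_families
    mg: CountMatrix
    mt: CountMatrix
    truth: SyntheticTruth
    spec: CommunitySpec
    seed: int

    def lineages(self) -> dict[str, Lineage]:
        return {
            r.gene_id: Lineage.from_string(r.lineage)
            for r in self.genes.itertuples(index=False)
            if r.lineage
        }

    def annotations(self) -> dict[str, str]:
        return {
            r.gene_id: r.ko_id for r in self.genes.itertuples(index=False) if r.ko_id
        }

    def gene_cazy(self) -> dict[str, list[str]]:
        return {
            r.gene_id: r.cazy_families.split(";")
            for r in self.genes.itertuples(index=False)
            if r.cazy_families
        }

    def lengths(self) -> dict[str, int]:
        return dict(zip(self.genes.gene_id, self.genes.length_bp))


def default_spec(**overrides) -> CommunitySpec:
    """The default healthy-vs-rotten community."""
    lin = Lineage.from_string
    fams = (
        FamilySpec("Polyporaceae", lin("Eukaryota;Basidiomycota;Agaricomycetes;Polyporales;Polyporaceae;Fomes"), "focal", 0.0, 0.0),
        FamilySpec("Burkholderiaceae", lin("Bacteria;Proteobacteria;Betaproteobacteria;Burkholderiales;Burkholderiaceae;Paraburkholderia"), "bacterial", 0.3, 10.7),
        FamilySpec("Microbacteriaceae", lin("Bacteria;Actinobacteria;Actinomycetia;Micrococcales;Microbacteriaceae;Curtobacterium"), "bacterial", 1.2, 9.7),
        FamilySpec("Sphingomonadaceae", lin("Bacteria;Proteobacteria;Alphaproteobacteria;Sphingomonadales;Sphingomonadaceae;Sphingomonas"), "bacterial", 0.1, 8.2),
        FamilySpec("Yersiniaceae", lin("Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacterales;Yersiniaceae;Serratia"), "bacterial", 0.3, 4.0),
        FamilySpec("Comamonadaceae", lin("Bacteria;Proteobacteria;Betaproteobacteria;Burkholderiales;Comamonadaceae;Variovorax"), "bacterial", 0.1, 4.0),
        FamilySpec("Rhodanobacteraceae", lin("Bacteria;Proteobacteria;Gammaproteobacteria;Lysobacterales;Rhodanobacteraceae;Rhodanobacter"), "bacterial", 0.1, 3.0),
        FamilySpec("Bradyrhizobiaceae", lin("Bacteria;Proteobacteria;Alphaproteobacteria;Hyphomicrobiales;Bradyrhizobiaceae;Bradyrhizobium"), "bacterial", 0.1, 3.0),
        FamilySpec("Xanthobacteraceae", lin("Bacteria;Proteobacteria;Alphaproteobacteria;Hyphomicrobiales;Xanthobacteraceae;Xanthobacter"), "bacterial", 0.1, 2.0),
        FamilySpec("Chitinophagaceae", lin("Bacteria;Bacteroidetes;Chitinophagia;Chitinophagales;Chitinophagaceae;Chitinophaga"), "bacterial", 0.1, 2.0),
        FamilySpec("Micromonosporaceae", lin("Bacteria;Actinobacteria;Actinomycetia;Micromonosporales;Micromonosporaceae;Actinoplanes"), "bacterial", 0.1, 2.0),
        FamilySpec("Streptomycetaceae", lin("Bacteria;Actinobacteria;Actinomycetia;Streptomycetales;Streptomycetaceae;Streptomyces"), "bacterial", 0.1, 2.0),
        FamilySpec("Hypocreaceae", lin("Eukaryota;Ascomycota;Sordariomycetes;Hypocreales;Hypocreaceae;Trichoderma"), "eukaryote", 0.15, 2.0),
        FamilySpec("Helotiaceae", lin("Eukaryota;Ascomycota;Leotiomycetes;Helotiales;Helotiaceae;Hymenoscyphus"), "eukaryote", 0.15, 2.0),
        FamilySpec("Tenebrionidae", lin("Eukaryota;Arthropoda;Insecta;Coleoptera;Tenebrionidae;Bolitophagus"), "arthropod", 0.05, 1.5),
        FamilySpec("Cerambycidae", lin("Eukaryota;Arthropoda;Insecta;Coleoptera;Cerambycidae;Rhagium"), "arthropod", 0.05, 0.5),
        FamilySpec("Pyroglyphidae", lin("Eukaryota;Arthropoda;Arachnida;Sarcoptiformes;Pyroglyphidae;Dermatophagoides"), "arthropod", 0.05, 0.5),
        FamilySpec(UNASSIGNED_POOL, None, "unassigned", 1.0, 5.0),
    )
    planted_modules = {
        "Burkholderiaceae": ("M00530", "M00531"),
        "Yersiniaceae": ("M00530",),
        "Comamonadaceae": ("M00531",),
        "Bradyrhizobiaceae": ("M00176", "M00175"),
        "Microbacteriaceae": ("M00345",),
        "Sphingomonadaceae": ("M00597",),
        "Rhodanobacteraceae": ("M00937",),
        "Xanthobacteraceae": ("M00935",),
    }
    # Denitrification split across two families: complete for the community,
    # complete for no single family.
    planted_kos = {
        "Burkholderiaceae": ("K00368", "K04561"),
        "Comamonadaceae": ("K02305", "K00376"),
    }
    planted_cazymes = (
        PlantedCazyme("Polyporaceae", ("GH5",), 2),
        PlantedCazyme("Polyporaceae", ("GH6",), 1),
        PlantedCazyme("Polyporaceae", ("GH7",), 2),
        PlantedCazyme("Polyporaceae", ("AA9",), 2),
        PlantedCazyme("Polyporaceae", ("GH16",), 2),
        PlantedCazyme("Polyporaceae", ("GH18",), 2),
        PlantedCazyme("Polyporaceae", ("GH47",), 1),
        PlantedCazyme("Tenebrionidae", ("GH18",), 13, mt_boost=True),
        PlantedCazyme("Tenebrionidae", ("GH16",), 3, mt_boost=True),
        PlantedCazyme("Cerambycidae", ("GH18",), 1, mt_boost=True),
        PlantedCazyme("Pyroglyphidae", ("GH18",), 1, mt_boost=True),
        PlantedCazyme("Micromonosporaceae", ("GH6", "GH18"), 1),
        PlantedCazyme("Micromonosporaceae", ("GH16",), 1),
        PlantedCazyme("Streptomycetaceae", ("GH16",), 1),
        PlantedCazyme("Chitinophagaceae", ("GH76",), 1),
        PlantedCazyme("Burkholderiaceae", ("GH23",), 1),
        PlantedCazyme("Burkholderiaceae", ("GH92",), 1),
        PlantedCazyme("Hypocreaceae", ("GH16",), 1),
    )
    kwargs = dict(
        families=fams,
        planted_modules=planted_modules,
        planted_kos=planted_kos,
        planted_cazymes=planted_cazymes,
    )
    kwargs.update(overrides)
    return CommunitySpec(**kwargs)


# ---------------------------------------------------------------------------
# generation


def _module_ko_needs(spec: CommunitySpec) -> dict[str, list[str]]:
    """KOs each family needs so its planted modules are satisfiable.

    Blacklisted KOs are withheld, which is exactly how modules such as
    nitrogen fixation are kept incomplete on purpose.
    """
    defs = {m.module_id: m.definition for m in load_default_modules()}
    needs: dict[str, list[str]] = {}
    for family, modules in spec.planted_modules.items():
        kos: set[str] = set()
        for mid in modules:
            if mid not in defs:
                raise ValueError(f"unknown planted module {mid}")
            kos |= required_kos(parse_definition(defs[mid]))
        needs[family] = sorted(kos - spec.omit_kos)
    for family, extra in spec.planted_kos.items():
        bad = set(extra) & spec.omit_kos
        merged = sorted(set(needs.get(family, [])) | (set(extra) - spec.omit_kos))
        needs[family] = merged
    return needs


def _build_gene_table(spec: CommunitySpec, rng: np.random.Generator) -> pd.DataFrame:
    repertoire = [k for k in load_default_repertoire() if k not in spec.omit_kos]
    needs = _module_ko_needs(spec)
    records = []
    gene_no = 0
    for fam in spec.families:
        fam_kos = needs.get(fam.label, [])
        if len(fam_kos) > spec.genes_per_family:
            raise ValueError(
                f"family {fam.label} needs {len(fam_kos)} planted KOs but has only "
                f"{spec.genes_per_family} genes"
            )
        lengths = np.clip(
            rng.lognormal(mean=6.9, sigma=0.7, size=spec.genes_per_family), 150, 30000
        ).astype(int)
        weights = rng.lognormal(mean=0.0, sigma=0.5, size=spec.genes_per_family)
        planted = [pc for pc in spec.planted_cazymes if pc.family == fam.label]
        caz_slots: list[tuple[str, bool]] = []
        for pc in planted:
            caz_slots.extend([(";".join(pc.cazy_families), pc.mt_boost)] * pc.n_genes)
        if len(caz_slots) > spec.genes_per_family:
            raise ValueError(f"family {fam.label}: too many planted CAZyme genes")
        for i in range(spec.genes_per_family):
            gene_no += 1
            ko = fam_kos[i] if i < len(fam_kos) else ""
            if not ko and fam.kind in ("bacterial", "focal") and rng.random() < 0.25:
                ko = repertoire[rng.integers(len(repertoire))]
            cazy, boost = caz_slots[i] if i < len(caz_slots) else ("", False)
            records.append(
                {
                    "gene_id": f"gene_{gene_no:05d}",
                    "family": fam.label,
                    "lineage": fam.lineage.to_string() if fam.lineage else "",
                    "length_bp": int(lengths[i]),
                    "weight": float(weights[i]),
                    "ko_id": ko,
                    "cazy_families": cazy,
                    "mt_boost": boost,
                }
            )
    return pd.DataFrame(records)


def _base_shares(spec: CommunitySpec, condition: str) -> pd.Series:
    focal = (
        spec.healthy_focal_share if condition == HEALTHY else spec.rotten_focal_share
    )
    weights = pd.Series(
        {
            f.label: (f.healthy_weight if condition == HEALTHY else f.rotten_weight)
            for f in spec.families
            if f.kind != "focal"
        },
        dtype=float,
    )
    shares = weights / weights.sum() * (1.0 - focal)
    shares[spec.focal_family.label] = focal
    return shares.reindex([f.label for f in spec.families]).fillna(0.0)


def _gene_probs(
    genes: pd.DataFrame, family_shares: pd.Series
) -> np.ndarray:
    w = (genes.length_bp * genes.weight).to_numpy(dtype=float)
    fam_totals = pd.Series(w).groupby(genes.family.values).transform("sum").to_numpy()
    share = family_shares.reindex(genes.family).to_numpy(dtype=float)
    return share * w / fam_totals


def generate(
    spec: CommunitySpec,
    n_healthy: int,
    n_rotten: int,
    seed: int,
) -> SyntheticBundle:
    """Generate a complete annotated community with planted truth."""
    if n_healthy + n_rotten < 2:
        raise ValueError("need at least 2 samples for downstream clustering")
    rng = np.random.default_rng(seed)
    genes = _build_gene_table(spec, rng)

    samples = [f"FB{i+1:02d}" for i in range(n_healthy + n_rotten)]
    conditions = [HEALTHY] * n_healthy + [ROTTEN] * n_rotten
    labels = dict(zip(samples, conditions))

    share_rows = []
    mg_counts = {}
    mt_counts = {}
    boost_mask = genes.mt_boost.to_numpy(dtype=bool)
    unassigned_mask = (genes.family == UNASSIGNED_POOL).to_numpy()
    for sample, condition in zip(samples, conditions):
        base = _base_shares(spec, condition)
        shares = _draw_shares(base, spec.overdispersion, rng)
        share_rows.append(shares)
        mg_counts[sample] = rng.multinomial(spec.depth, _gene_probs(genes, shares))

        mt_shares = _draw_shares(base, spec.overdispersion, rng)
        p = _gene_probs(genes, mt_shares)
        if condition == ROTTEN:
            p = _rotten_mt_probs(p, genes, boost_mask, unassigned_mask, spec)
        mt_counts[sample] = rng.multinomial(spec.depth, p)

    mg = pd.DataFrame(mg_counts, index=genes.gene_id).T
    mt = pd.DataFrame(mt_counts, index=genes.gene_id).T
    for frame in (mg, mt):
        frame.index.name = "sample"
        frame.columns.name = "gene_id"
    truth = SyntheticTruth(
        labels=labels,
        family_shares=pd.DataFrame(share_rows, index=samples),
        planted_modules=dict(spec.planted_modules),
        planted_cazymes=spec.planted_cazymes,
    )
    public = genes.drop(columns=["weight", "mt_boost"])
    return SyntheticBundle(
        genes=public,
        mg=CountMatrix(mg, layer="metagenome"),
        mt=CountMatrix(mt, layer="metatranscriptome"),
        truth=truth,
        spec=spec,
        seed=seed,
    )


def _draw_shares(
    base: pd.Series, overdispersion: float, rng: np.random.Generator
) -> pd.Series:
    if overdispersion == 0:
        return base.copy()
    positive = base > 0
    alpha = base[positive].to_numpy() / overdispersion
    drawn = pd.Series(0.0, index=base.index)
    drawn[positive] = rng.dirichlet(alpha)
    return drawn


def _rotten_mt_probs(
    p: np.ndarray,
    genes: pd.DataFrame,
    boost_mask: np.ndarray,
    unassigned_mask: np.ndarray,
    spec: CommunitySpec,
) -> np.ndarray:
    """Concentrate rotten MT mass on unassigned genes and boosted CAZymes."""
    u = spec.unassigned_mt_fraction
    b = spec.cazyme_mt_boost if boost_mask.any() else 0.0
    rest_mask = ~(boost_mask | unassigned_mask)
    out = np.zeros_like(p)
    w = (genes.length_bp * genes.weight).to_numpy(dtype=float)
    if unassigned_mask.any():
        wu = w[unassigned_mask]
        out[unassigned_mask] = u * wu / wu.sum()
    else:
        u = 0.0
    if b > 0:
        wb = w[boost_mask]
        out[boost_mask] = b * wb / wb.sum()
    rest = p[rest_mask]
    out[rest_mask] = (1.0 - u - b) * rest / rest.sum()
    return out


def make_transitional(
    bundle: SyntheticBundle,
    sample: str,
    mg_focal_share: float,
    mt_focal_share: float,
) -> SyntheticBundle:
    """Rewrite one sample so its MG/MT focal shares hit the given targets.

    Counts are rescaled deterministically (largest-remainder rounding) so
    per-sample totals are preserved exactly; the truth condition becomes
    ``transitional``.
    """
    for share in (mg_focal_share, mt_focal_share):
        if not 0 <= share <= 1:
            raise ValueError("shares must lie in [0, 1]")
    focal_label = bundle.spec.focal_family.label
    focal_mask = (bundle.genes.family == focal_label).to_numpy()
    lengths = bundle.genes.length_bp.to_numpy(dtype=float)

    mg = bundle.mg.data.copy()
    mt = bundle.mt.data.copy()
    mg.loc[sample] = _retarget(mg.loc[sample].to_numpy(), focal_mask, mg_focal_share, lengths)
    mt.loc[sample] = _retarget(mt.loc[sample].to_numpy(), focal_mask, mt_focal_share, lengths)

    labels = dict(bundle.truth.labels)
    labels[sample] = TRANSITIONAL
    shares = bundle.truth.family_shares.copy()
    truth = SyntheticTruth(
        labels=labels,
        family_shares=shares,
        planted_modules=bundle.truth.planted_modules,
        planted_cazymes=bundle.truth.planted_cazymes,
    )
    return replace(
        bundle,
        mg=CountMatrix(mg, layer=bundle.mg.layer),
        mt=CountMatrix(mt, layer=bundle.mt.layer),
        truth=truth,
    )


def _retarget(
    row: np.ndarray, focal_mask: np.ndarray, share: float, lengths: np.ndarray
) -> np.ndarray:
    depth = int(row.sum())
    target_focal = share * depth
    focal_total = row[focal_mask].sum()
    other_total = depth - focal_total
    real = np.zeros_like(row, dtype=float)
    if focal_total > 0:
        real[focal_mask] = row[focal_mask] * target_focal / focal_total
    elif target_focal > 0:
        lw = lengths[focal_mask]
        real[focal_mask] = target_focal * lw / lw.sum()
    if other_total > 0:
        real[~focal_mask] = row[~focal_mask] * (depth - target_focal) / other_total
    return _largest_remainder(real, depth)


def _largest_remainder(real: np.ndarray, total: int) -> np.ndarray:
    floors = np.floor(real).astype(np.int64)
    shortfall = total - int(floors.sum())
    if shortfall > 0:
        order = np.lexsort((np.arange(len(real)), -(real - floors)))
        floors[order[:shortfall]] += 1
    return floors


# ---------------------------------------------------------------------------
# serialisation


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every external file downstream stages read.

    Emits FASTA, BLAST outfmt 6 hits with a decoy second hit per gene,
    taxmap, KO/CAZyme annotation TSVs, count matrices, sample metadata and
    the truth record.  Deterministic for a fixed bundle.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / fname for name, fname in [
        ("fasta", "genes.fasta"),
        ("annotations", "annotations.tsv"),
        ("hits", "hits.tsv"),
        ("taxmap", "taxmap.tsv"),
        ("counts_mg", "counts_mg.tsv"),
        ("counts_mt", "counts_mt.tsv"),
        ("kofam", "kofam.tsv"),
        ("dbcan", "dbcan.tsv"),
        ("metadata", "metadata.tsv"),
        ("truth", "truth.json"),
    ]}

    rng = np.random.default_rng([bundle.seed, 101])
    alphabet = np.array(list("ACGT"))
    with open(paths["fasta"], "w") as fh:
        for rec in bundle.genes.itertuples(index=False):
            seq = "".join(alphabet[rng.integers(0, 4, size=rec.length_bp)])
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    bundle.genes.to_csv(paths["annotations"], sep="\t", index=False)

    hits: list[BlastHit] = []
    taxmap: dict[str, Lineage] = {}
    assigned = bundle.genes[bundle.genes.lineage != ""]
    labels = list(dict.fromkeys(assigned.family))
    for label in labels:
        lineage = assigned.loc[assigned.family == label, "lineage"].iloc[0]
        taxmap[f"{label}|rep"] = Lineage.from_string(lineage)
    for i, rec in enumerate(assigned.itertuples(index=False)):
        alen = max(rec.length_bp // 3, 30)
        hits.append(BlastHit(rec.gene_id, f"{rec.family}|rep", 98.5, alen, 2, 0, 1, alen, 1, alen, 1e-80, 250.0))
        decoy = labels[(labels.index(rec.family) + 1 + i % (len(labels) - 1)) % len(labels)]
        if decoy == rec.family:
            decoy = labels[(labels.index(rec.family) + 1) % len(labels)]
        hits.append(BlastHit(rec.gene_id, f"{decoy}|rep", 71.0, alen, 12, 1, 1, alen, 1, alen, 1e-30, 140.0))
    io_formats.write_blast6(hits, paths["hits"])
    io_formats.write_taxmap_tsv(taxmap, paths["taxmap"])

    io_formats.write_counts_tsv(bundle.mg.data, paths["counts_mg"])
    io_formats.write_counts_tsv(bundle.mt.data, paths["counts_mt"])

    kofam_rows = [
        KofamRow(r.gene_id, r.ko_id, 120.5, 100.0, 1e-12)
        for r in bundle.genes.itertuples(index=False)
        if r.ko_id
    ]
    # a few sub-threshold decoy rows that the filter must drop
    for r in list(bundle.genes.itertuples(index=False))[:3]:
        kofam_rows.append(KofamRow(r.gene_id, "K09999", 80.0, 100.0, 1e-12))
        kofam_rows.append(KofamRow(r.gene_id, "K09998", 150.0, 100.0, 1e-3))
    io_formats.write_kofam_tsv(kofam_rows, paths["kofam"])

    dbcan_rows = [
        DbcanRow(r.gene_id, fam)
        for r in bundle.genes.itertuples(index=False)
        if r.cazy_families
        for fam in r.cazy_families.split(";")
    ]
    io_formats.write_dbcan_tsv(dbcan_rows, paths["dbcan"])

    meta = pd.DataFrame(
        {
            "sample": list(bundle.truth.labels),
            "putative_status": [
                HEALTHY if c == TRANSITIONAL else c for c in bundle.truth.labels.values()
            ],
            "condition": list(bundle.truth.labels.values()),
            "mt_reads": [int(bundle.mt.data.loc[s].sum()) for s in bundle.truth.labels],
        }
    )
    meta.to_csv(paths["metadata"], sep="\t", index=False)

    truth_obj = {
        "labels": bundle.truth.labels,
        "family_shares": {
            s: dict(bundle.truth.family_shares.loc[s])
            for s in bundle.truth.family_shares.index
        },
        "planted_modules": {k: list(v) for k, v in bundle.truth.planted_modules.items()},
        "planted_cazymes": [
            {
                "family": pc.family,
                "cazy_families": list(pc.cazy_families),
                "n_genes": pc.n_genes,
                "mt_boost": pc.mt_boost,
            }
            for pc in bundle.truth.planted_cazymes
        ],
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
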