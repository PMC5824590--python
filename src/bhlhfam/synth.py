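"""Seeded generator of a synthetic diploid-A / diploid-D / allotetraploid
gene-family dataset with known ground truth for every downstream stage.

The generator emulates the structure of a transcription-factor family
surveyed across two diploid progenitor genomes (A and D) and the
allotetraploid formed from them:

* every gene carries one planted 61-aa bHLH domain whose basic-region
  composition and key residues realise a chosen DNA-binding category;
* gene models plant intron positions/phases inside the domain-encoding CDS;
* the tetraploid carries an A- and a D-subgenome copy of each family
  (homeologs, suffix ``_At``/``_Dt``); within-lineage copies differ only
  synonymously, while the A and D lineages differ at a few flank residues;
* subgenome-internal duplicate pairs are planted at chosen synonymous
  divergence (Ks) by placing exact numbers of synonymous third-position
  substitutions;
* expression count matrices plant per-pair A/D bias (a uniform fold applied
  across conditions, which leaves the pair correlation intact) and a target
  Pearson correlation between profiles, with negative-binomial noise; FPKM is
  derived as count * 1e9 / (gene_length_bp * library_size).

All randomness flows from a single integer seed; re-running with the same
configuration is byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from ._codon import (
    split_codons,
    synonymous_alternatives,
    synonymous_sites,
)
from .consensus import (
    ALPHABET,
    BASIC_REGION_LENGTH,
    DOMAIN_LENGTH,
    KEY_POSITIONS,
    default_model,
)
from .domains import BASIC_RESIDUES, CATEGORIES, DNA_BINDING_MIN_BASIC
from .structure import IntronPattern

_NONBASIC_POOL = "QENSATDG"
_NON_H_POOL = "AQNSE"     # breaks the G-box His-5 requirement
_NON_E_POOL = "AQNSD"     # breaks the E-box Glu-9 requirement
_NON_R16_POOL = "QNSA"    # SREBP-like: E-box residues but no Arg-16

from ._codon import CODON_TO_AA  # noqa: E402

_AA_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    _AA_CODONS.setdefault(_aa, []).append(_codon)


def _check_mix(name: str, values) -> None:
    if any(v < 0 for v in values):
        raise ValueError(f"{name} proportions must be non-negative")
    if abs(sum(values) - 1.0) > 1e-9:
        raise ValueError(f"{name} proportions must sum to 1")


@dataclass
class FamilyConfig:
    """Study conditions for one synthetic species trio.

    ``binding_mix`` orders the four DNA-binding categories as
    (G-box, E-box-non-G-box, non-E-box, non-DNA); the default reproduces the
    category proportions observed in an allotetraploid cotton bHLH survey
    (258/60/67/47 of 432).  ``bias_mix`` orders homeolog bias as
    (Ahigh, equal, Dhigh), default 53/67/69 of 189.  ``ks_targets`` plants one
    subgenome-internal duplicate pair per value (first half in the
    A-subgenome, second half in the D-subgenome).
    """

    n_genes_per_genome: int = 60
    domain_length: int = DOMAIN_LENGTH
    binding_mix: tuple[float, float, float, float] = (
        258 / 432, 60 / 432, 67 / 432, 47 / 432,
    )
    intron_pattern_mix: tuple[tuple[str, float], ...] = (
        ("-", 0.12),
        ("10:0", 0.28),
        ("19:0", 0.18),
        ("10:0;27:0", 0.16),
        ("10:0;27:1", 0.08),
        ("5:0;19:0;33:0", 0.08),
        ("8:1", 0.06),
        ("5:2;19:0;33:0;46:0", 0.04),
    )
    ks_targets: tuple[float, ...] = tuple(
        [0.05] + list(np.round(np.linspace(0.32, 0.92, 15), 4))
        + [0.15] + list(np.round(np.linspace(0.35, 0.95, 15), 4))
    )
    bias_mix: tuple[float, float, float] = (53 / 189, 67 / 189, 69 / 189)
    n_conditions: int = 12
    seed: int = 0

    # noise / effect-size conditions
    dispersion: float | None = 0.1      # NB dispersion; 0 = Poisson, None = noise off
    library_size: float = 2.0e7
    bias_fold: float = 4.0              # planted fold for biased homeolog pairs
    base_mean: float = 300.0            # baseline per-condition count scale
    condition_sd: float = 0.9           # log-scale between-condition spread
    conserved_r: float = 0.9            # planted correlation, conserved pairs
    diverged_r: float = 0.1             # planted correlation, diverged pairs
    homeolog_conserved_frac: float = 165 / 189
    dup_conserved_frac: float = 67 / 215
    homeolog_ks: float = 0.032          # A/D progenitor split
    ortholog_ks: float = 0.0065         # diploid vs subgenome copy
    srebp_rate: float = 0.01
    n_flank_subs: int = 4
    basic_count_dna: tuple[tuple[int, float], ...] = (
        (5, 0.30), (6, 0.30), (7, 0.25), (8, 0.15),
    )
    basic_count_nondna: tuple[tuple[int, float], ...] = (
        (2, 1 / 3), (3, 1 / 3), (4, 1 / 3),
    )

    def __post_init__(self) -> None:
        if self.n_genes_per_genome < 1:
            raise ValueError("need at least one gene per genome")
        if self.domain_length != DOMAIN_LENGTH:
            raise ValueError(f"domain_length must be {DOMAIN_LENGTH}")
        _check_mix("binding_mix", self.binding_mix)
        _check_mix("intron_pattern_mix", [p for _, p in self.intron_pattern_mix])
        _check_mix("bias_mix", self.bias_mix)
        for ks in self.ks_targets:
            if not 0.0 < ks <= 3.0:
                raise ValueError(f"ks_targets must lie in (0, 3.0]; got {ks}")
        if self.n_conditions < 3:
            raise ValueError("n_conditions must be >= 3 (Pearson r needs df >= 1)")
        # feasibility of the binding categories against the planted counts
        _check_mix("basic_count_dna", [p for _, p in self.basic_count_dna])
        _check_mix("basic_count_nondna", [p for _, p in self.basic_count_nondna])
        if min(k for k, _ in self.basic_count_dna) < DNA_BINDING_MIN_BASIC:
            raise ValueError(
                "binding_mix infeasible for DNA-binding categories "
                "(G-box/E-box-non-G-box/non-E-box): planted basic-residue count "
                f"below the DNA-binding threshold {DNA_BINDING_MIN_BASIC}"
            )
        if max(k for k, _ in self.basic_count_nondna) >= DNA_BINDING_MIN_BASIC:
            raise ValueError(
                "binding_mix infeasible for category non-DNA: planted "
                f"basic-residue count reaches the DNA-binding threshold "
                f"{DNA_BINDING_MIN_BASIC}"
            )
        for pat, _ in self.intron_pattern_mix:
            IntronPattern.from_key(pat)  # validates

    @property
    def conditions(self) -> list[str]:
        return [f"T{j + 1:02d}" for j in range(self.n_conditions)]


@dataclass
class GroundTruth:
    """Planted truth: one record per generated gene and pair."""

    genes: pd.DataFrame          # gene_id, category, basic_count, srebp, intron_key, ...
    homeolog_pairs: pd.DataFrame  # gene_a, gene_d, bias, target_r
    dup_pairs: pd.DataFrame       # gene1, gene2, subgenome, target_ks, target_r
    ortholog_pairs: pd.DataFrame  # diploid_gene, subgenome_gene, lineage


@dataclass
class SyntheticFamily:
    config: FamilyConfig
    genes: pd.DataFrame
    gff: dict[str, str]
    homeolog_pairs: pd.DataFrame
    dup_pairs: pd.DataFrame
    ortholog_pairs: pd.DataFrame
    counts: pd.DataFrame
    fpkm: pd.DataFrame
    library_sizes: pd.Series
    expression_truth: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def ground_truth(self) -> GroundTruth:
        cols = ["genome", "subgenome", "family", "category", "basic_count",
                "srebp_like", "intron_key", "domain_start"]
        return GroundTruth(
            genes=self.genes[cols].copy(),
            homeolog_pairs=self.homeolog_pairs.copy(),
            dup_pairs=self.dup_pairs.copy(),
            ortholog_pairs=self.ortholog_pairs.copy(),
        )

    def proteins(self, genome: str) -> dict[str, str]:
        sel = self.genes[self.genes.genome == genome]
        return dict(zip(sel.index, sel.protein))

    def cds(self, genome: str) -> dict[str, str]:
        sel = self.genes[self.genes.genome == genome]
        return dict(zip(sel.index, sel.cds))

    def write(self, outdir: str | Path) -> None:
        """Write FASTA/GFF3/TSV artifacts (text formats, byte-deterministic)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for genome in ("A", "D", "AD"):
            _write_fasta(outdir / f"{genome}.proteins.fasta", self.proteins(genome))
            _write_fasta(outdir / f"{genome}.cds.fasta", self.cds(genome))
            (outdir / f"{genome}.gff3").write_text(self.gff[genome])
        self.homeolog_pairs[["gene_a", "gene_d"]].to_csv(
            outdir / "homeolog_pairs.tsv", sep="\t", index=False)
        for sub in ("A", "D"):
            sel = self.dup_pairs[self.dup_pairs.subgenome == sub]
            sel[["gene1", "gene2"]].to_csv(
                outdir / f"dup_pairs_{sub}.tsv", sep="\t", index=False)
        self.ortholog_pairs.to_csv(outdir / "ortholog_truth.tsv", sep="\t", index=False)
        self.counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene_id")
        self.fpkm.to_csv(outdir / "fpkm.tsv", sep="\t", index_label="gene_id",
                         float_format="%.6f")
        self.library_sizes.rename("library_size").to_csv(
            outdir / "library_sizes.tsv", sep="\t", index_label="condition")
        truth = outdir / "truth"
        truth.mkdir(exist_ok=True)
        gt = self.ground_truth
        gt.genes.to_csv(truth / "genes.tsv", sep="\t", index_label="gene_id")
        gt.homeolog_pairs.to_csv(truth / "homeolog_pairs.tsv", sep="\t", index=False)
        gt.dup_pairs.to_csv(truth / "dup_pairs.tsv", sep="\t", index=False)


def _write_fasta(path: Path, seqs: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n{seqs[name]}\n")


# ---------------------------------------------------------------------------
# domain / sequence construction


def _sample_domain(rng: np.random.Generator, category: str, basic_target: int,
                   srebp: bool, profile: np.ndarray) -> str:
    """Sample a 61-aa domain realising exactly one binding category."""
    aas = list(ALPHABET)
    residues = [
        str(rng.choice(aas, p=profile[p])) for p in range(DOMAIN_LENGTH)
    ]
    forced: set[int] = set()  # 0-based positions not to touch when adjusting

    def force(pos1: int, aa: str) -> None:
        residues[pos1 - 1] = aa
        forced.add(pos1 - 1)

    if category == "G-box":
        force(KEY_POSITIONS["his5"], "H")
        force(KEY_POSITIONS["glu9"], "E")
        force(KEY_POSITIONS["arg12"], "R")
        force(KEY_POSITIONS["arg13"], "R")
        force(KEY_POSITIONS["arg16"],
              str(rng.choice(list(_NON_R16_POOL))) if srebp else "R")
    elif category == "E-box-non-G-box":
        force(KEY_POSITIONS["his5"], str(rng.choice(list(_NON_H_POOL))))
        force(KEY_POSITIONS["glu9"], "E")
        force(KEY_POSITIONS["arg12"], "R")
        force(KEY_POSITIONS["arg16"],
              str(rng.choice(list(_NON_R16_POOL))) if srebp else "R")
    elif category == "non-E-box":
        force(KEY_POSITIONS["glu9"], str(rng.choice(list(_NON_E_POOL))))
    elif category != "non-DNA":
        raise ValueError(f"unknown binding category {category!r}")

    # adjust the basic-region residue count to the planted target
    free = [i for i in range(BASIC_REGION_LENGTH) if i not in forced]
    count = sum(1 for i in range(BASIC_REGION_LENGTH) if residues[i] in BASIC_RESIDUES)
    rng.shuffle(free)
    for i in free:
        if count == basic_target:
            break
        if count > basic_target and residues[i] in BASIC_RESIDUES:
            residues[i] = str(rng.choice(list(_NONBASIC_POOL)))
            count -= 1
        elif count < basic_target and residues[i] not in BASIC_RESIDUES:
            residues[i] = str(rng.choice(["K", "R", "H"], p=[0.45, 0.45, 0.1]))
            count += 1
    if count != basic_target:
        raise ValueError(
            f"category {category}: cannot realise basic-residue count {basic_target}"
        )
    return "".join(residues)


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(str(rng.choice(_AA_CODONS[aa])) for aa in protein)


def mutate_cds_to_ks(cds: str, target_ks: float, seed: int) -> str:
    """Synonymously diverge a CDS so the expected NG86 Ks equals ``target_ks``.

    The Jukes-Cantor relation is inverted to the required proportion of
    synonymous differences pS = (3/4)(1 - exp(-4 Ks / 3)); round(pS * S)
    distinct codons then receive one synonymous third-position substitution
    each.  Third-position synonymous swaps preserve every codon's synonymous
    site count, so the NG86 estimate of the returned pair is deterministic up
    to the rounding of the substitution count.  The translation is unchanged.
    """
    if not 0.0 < target_ks <= 3.0:
        raise ValueError(f"target Ks must lie in (0, 3.0]; got {target_ks}")
    codons = split_codons(cds)
    from ._codon import STOP_CODONS
    if codons and codons[-1] in STOP_CODONS:
        raise ValueError("CDS must not end in a stop codon for divergence planting")
    rng = np.random.default_rng(seed)
    S = sum(synonymous_sites(c) for c in codons)
    p_s = 0.75 * (1.0 - math.exp(-4.0 * target_ks / 3.0))
    k = max(1, round(p_s * S))
    candidates = [i for i, c in enumerate(codons) if synonymous_alternatives(c, 2)]
    if k > len(candidates):
        raise ValueError(
            f"sequence too short: {k} synonymous substitutions required but only "
            f"{len(candidates)} codons admit one"
        )
    chosen = rng.choice(len(candidates), size=k, replace=False)
    out = list(codons)
    for j in sorted(int(x) for x in chosen):
        i = candidates[j]
        alts = synonymous_alternatives(out[i], 2)
        base = str(rng.choice(alts))
        out[i] = out[i][:2] + base
    return "".join(out)


# ---------------------------------------------------------------------------
# gene models


def _intron_offsets(pattern: IntronPattern, domain_start: int) -> list[int]:
    """CDS base offsets (coding bases 5' of each junction) for a planted pattern."""
    return [
        3 * (domain_start + pos - 1) + phase
        for pos, phase in zip(pattern.positions, pattern.phases)
    ]


def _exon_intervals(start: int, segments: list[int], introns: list[int],
                    strand: str) -> list[tuple[int, int]]:
    """Genomic CDS intervals in transcript order."""
    out = []
    if strand == "+":
        g = start
        for i, seg in enumerate(segments):
            out.append((g, g + seg - 1))
            g += seg
            if i < len(introns):
                g += introns[i]
    else:
        total = sum(segments) + sum(introns)
        g = start + total - 1
        for i, seg in enumerate(segments):
            out.append((g - seg + 1, g))
            g -= seg
            if i < len(introns):
                g -= introns[i]
    return out


def _gff_entry(gene_id: str, chrom: str, strand: str,
               exons_tx_order: list[tuple[int, int]]) -> str:
    lo = min(s for s, _ in exons_tx_order)
    hi = max(e for _, e in exons_tx_order)
    lines = [
        f"{chrom}\tbhlhfam\tgene\t{lo}\t{hi}\t.\t{strand}\t.\tID={gene_id}",
        f"{chrom}\tbhlhfam\tmRNA\t{lo}\t{hi}\t.\t{strand}\t.\t"
        f"ID={gene_id}.t1;Parent={gene_id}",
    ]
    # GFF3 phase column: bases to remove to reach the next codon start
    cum = 0
    feats = []
    for s, e in exons_tx_order:
        phase = (3 - cum % 3) % 3
        feats.append((s, e, phase))
        cum += e - s + 1
    for s, e, phase in sorted(feats):
        lines.append(
            f"{chrom}\tbhlhfam\texon\t{s}\t{e}\t.\t{strand}\t.\tParent={gene_id}.t1"
        )
        lines.append(
            f"{chrom}\tbhlhfam\tCDS\t{s}\t{e}\t.\t{strand}\t{phase}\t"
            f"Parent={gene_id}.t1"
        )
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# expression


def generate_expression(
    pairs: list[tuple[str, str]],
    bias_mix,
    correlation_targets,
    library_sizes,
    seed: int,
    *,
    n_conditions: int = 12,
    dispersion: float | None = 0.1,
    bias_fold: float = 4.0,
    gene_lengths: dict[str, int] | None = None,
    base_mean: float = 300.0,
    condition_sd: float = 0.9,
    bias_categories: list[str] | None = None,
    satellites: list[tuple[str, str, float]] | None = None,
    conditions: list[str] | None = None,
):
    """Plant per-pair bias and correlation into count and FPKM matrices.

    ``pairs`` are (A-copy, D-copy) gene ids.  ``bias_mix`` is (Ahigh, equal,
    Dhigh) proportions used to sample a category per pair unless
    ``bias_categories`` gives them explicitly.  ``correlation_targets`` is a
    scalar or per-pair list of target Pearson correlations for the pair's
    latent condition profiles.  A biased pair's favoured copy is scaled by a
    constant ``bias_fold`` across every condition (which preserves the planted
    correlation).  ``satellites`` plants extra genes correlated with an
    already-generated anchor (used for subgenome-internal duplicates).

    Counts are negative-binomial with the given dispersion (0 gives Poisson,
    None disables noise); FPKM = count * 1e9 / (gene_length_bp * library_size).

    Returns (counts, fpkm, truth) DataFrames.
    """
    rng = np.random.default_rng(seed)
    lib = np.asarray(library_sizes, dtype=float)
    if lib.shape == ():
        lib = np.full(n_conditions, float(lib))
    if lib.size != n_conditions:
        raise ValueError("one library size per condition required")
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    if conditions is None:
        conditions = [f"T{j + 1:02d}" for j in range(n_conditions)]
    if bias_categories is None:
        _check_mix("bias_mix", bias_mix)
        bias_categories = [
            str(rng.choice(["Ahigh", "equal", "Dhigh"], p=list(bias_mix)))
            for _ in pairs
        ]
    if np.isscalar(correlation_targets):
        correlation_targets = [float(correlation_targets)] * len(pairs)
    if len(correlation_targets) != len(pairs) or len(bias_categories) != len(pairs):
        raise ValueError("per-pair parameter lists must match the pair list")

    gene_lengths = gene_lengths or {}
    latent: dict[str, np.ndarray] = {}
    scales: dict[str, float] = {}
    means: dict[str, np.ndarray] = {}

    def profile(base: float, x: np.ndarray, fold: float) -> np.ndarray:
        return base * np.exp(condition_sd * x - condition_sd**2 / 2.0) * fold

    truth_rows = []
    for (ga, gd), cat, r in zip(pairs, bias_categories, correlation_targets):
        if not -1.0 <= r <= 1.0:
            raise ValueError("correlation targets must lie in [-1, 1]")
        base = float(rng.lognormal(math.log(base_mean), 0.5))
        x = rng.standard_normal(n_conditions)
        z = r * x + math.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n_conditions)
        if cat == "Ahigh":
            fa, fd = math.sqrt(bias_fold), 1.0 / math.sqrt(bias_fold)
        elif cat == "Dhigh":
            fa, fd = 1.0 / math.sqrt(bias_fold), math.sqrt(bias_fold)
        elif cat == "equal":
            fa = fd = 1.0
        else:
            raise ValueError(f"unknown bias category {cat!r}")
        latent[ga], latent[gd] = x, z
        scales[ga] = scales[gd] = base
        means[ga] = profile(base, x, fa)
        means[gd] = profile(base, z, fd)
        truth_rows.append({"gene_a": ga, "gene_d": gd, "bias": cat,
                           "target_r": r, "fold": bias_fold if cat != "equal" else 1.0})

    for anchor, new, r in satellites or ():
        if anchor not in latent:
            raise KeyError(f"satellite anchor {anchor} has no generated profile")
        x = latent[anchor]
        z = r * x + math.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n_conditions)
        latent[new] = z
        scales[new] = scales[anchor]
        means[new] = profile(scales[anchor], z, 1.0)

    gene_ids = list(means)
    mean_mat = np.vstack([means[g] for g in gene_ids])
    if dispersion is None:
        counts = np.rint(mean_mat).astype(np.int64)
    elif dispersion == 0:
        counts = rng.poisson(mean_mat).astype(np.int64)
    elif dispersion > 0:
        n_param = 1.0 / dispersion
        p_param = n_param / (n_param + mean_mat)
        counts = rng.negative_binomial(n_param, p_param).astype(np.int64)
    else:
        raise ValueError("dispersion must be None or >= 0")

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=conditions)
    lengths = np.array([float(gene_lengths.get(g, 1000)) for g in gene_ids])
    fpkm = counts * 1e9 / (lengths[:, None] * lib[None, :])
    fpkm_df = pd.DataFrame(fpkm, index=gene_ids, columns=conditions)
    truth = pd.DataFrame(truth_rows)
    return counts_df, fpkm_df, truth


# ---------------------------------------------------------------------------
# family generation


def generate_family(config: FamilyConfig) -> SyntheticFamily:
    """Generate the full synthetic species trio with ground truth."""
    master = np.random.SeedSequence(config.seed)
    ss_seq, ss_mut, ss_expr, ss_struct = master.spawn(4)
    rng = np.random.default_rng(ss_seq)
    rng_mut = np.random.default_rng(ss_mut)
    rng_struct = np.random.default_rng(ss_struct)
    profile = default_model().profile

    n = config.n_genes_per_genome
    cat_names = list(CATEGORIES)
    dna_counts = [k for k, _ in config.basic_count_dna]
    dna_probs = [p for _, p in config.basic_count_dna]
    nondna_counts = [k for k, _ in config.basic_count_nondna]
    nondna_probs = [p for _, p in config.basic_count_nondna]
    pattern_keys = [k for k, _ in config.intron_pattern_mix]
    pattern_probs = [p for _, p in config.intron_pattern_mix]

    fam_rows = []
    for i in range(n):
        category = str(rng.choice(cat_names, p=list(config.binding_mix)))
        if category == "non-DNA":
            basic = int(rng.choice(nondna_counts, p=nondna_probs))
            srebp = False
        else:
            basic = int(rng.choice(dna_counts, p=dna_probs))
            srebp = (
                category in ("G-box", "E-box-non-G-box")
                and rng.random() < config.srebp_rate
            )
        domain = _sample_domain(rng, category, basic, srebp, profile)
        left = "".join(rng.choice(list(ALPHABET), size=int(rng.integers(60, 110))))
        right = "".join(rng.choice(list(ALPHABET), size=int(rng.integers(70, 130))))
        base_prot = left + domain + right
        dstart = len(left)
        # lineage-specific flank substitutions so A- and D-lineage proteins
        # are distinguishable by alignment score
        flanks = [p for p in range(len(base_prot)) if not dstart <= p < dstart + DOMAIN_LENGTH]
        subs = rng.choice(flanks, size=2 * config.n_flank_subs, replace=False)
        a_prot = list(base_prot)
        d_prot = list(base_prot)
        for p in subs[:config.n_flank_subs]:
            a_prot[p] = str(rng.choice([a for a in ALPHABET if a != base_prot[p]]))
        for p in subs[config.n_flank_subs:]:
            d_prot[p] = str(rng.choice([a for a in ALPHABET if a != base_prot[p]]))
        a_prot, d_prot = "".join(a_prot), "".join(d_prot)

        at_cds = _reverse_translate(rng, a_prot)
        dt_cds = list(split_codons(at_cds))
        for p, (aa_a, aa_d) in enumerate(zip(a_prot, d_prot)):
            if aa_a != aa_d:
                dt_cds[p] = str(rng.choice(_AA_CODONS[aa_d]))
        dt_cds = mutate_cds_to_ks(
            "".join(dt_cds), config.homeolog_ks, int(rng_mut.integers(2**31))
        )
        ga_cds = mutate_cds_to_ks(at_cds, config.ortholog_ks, int(rng_mut.integers(2**31)))
        gd_cds = mutate_cds_to_ks(dt_cds, config.ortholog_ks, int(rng_mut.integers(2**31)))
        pattern = str(rng.choice(pattern_keys, p=pattern_probs))
        fam_rows.append(
            dict(family=i, category=category, basic=basic, srebp=srebp,
                 pattern=pattern, domain_start=dstart,
                 a_prot=a_prot, d_prot=d_prot,
                 at_cds=at_cds, dt_cds=dt_cds, ga_cds=ga_cds, gd_cds=gd_cds)
        )

    # duplicate pairs: anchors cycle over families; first half A, second half D
    n_dup = len(config.ks_targets)
    n_dup_a = (n_dup + 1) // 2
    dup_rows = []
    for j, target in enumerate(config.ks_targets):
        sub = "A" if j < n_dup_a else "D"
        fam = fam_rows[(j if sub == "A" else j - n_dup_a) % n]
        anchor_id = f"GH{fam['family'] + 1:04d}_{'At' if sub == 'A' else 'Dt'}"
        dup_id = f"GH{9001 + j:04d}_{'At' if sub == 'A' else 'Dt'}"
        anchor_cds = fam["at_cds"] if sub == "A" else fam["dt_cds"]
        dup_cds = mutate_cds_to_ks(anchor_cds, target, int(rng_mut.integers(2**31)))
        dup_rows.append(
            dict(gene1=anchor_id, gene2=dup_id, subgenome=sub, target_ks=target,
                 family=fam["family"], cds=dup_cds,
                 protein=fam["a_prot"] if sub == "A" else fam["d_prot"],
                 category=fam["category"], basic=fam["basic"], srebp=fam["srebp"],
                 pattern=fam["pattern"], domain_start=fam["domain_start"])
        )

    # assemble per-gene table + gene models
    gene_rows: list[dict] = []
    gff_entries: dict[str, list[str]] = {"A": [], "D": [], "AD": []}
    cursors: dict[str, int] = {}

    def add_gene(gene_id, genome, subgenome, chrom, family, protein, cds,
                 dstart, category, basic, srebp, pattern_key, is_dup):
        pattern = IntronPattern.from_key(pattern_key)
        offsets = _intron_offsets(pattern, dstart)
        L = len(cds)
        segments = [b - a for a, b in zip([0] + offsets, offsets + [L])]
        introns = [int(rng_struct.integers(80, 400)) for _ in offsets]
        strand = "+" if rng_struct.random() < 0.5 else "-"
        start = cursors.get(chrom, 1)
        exons = _exon_intervals(start, segments, introns, strand)
        cursors[chrom] = start + L + sum(introns) + 3000
        gff_entries[genome].append(_gff_entry(gene_id, chrom, strand, exons))
        gene_rows.append(
            dict(gene_id=gene_id, genome=genome, subgenome=subgenome, chrom=chrom,
                 family=family, strand=strand, protein=protein, cds=cds,
                 domain_start=dstart, category=category, basic_count=basic,
                 srebp_like=srebp, intron_key=pattern_key, is_duplicate=is_dup)
        )

    ortho_rows = []
    homeo_rows = []
    for fam in fam_rows:
        i = fam["family"]
        common = (fam["domain_start"], fam["category"], fam["basic"],
                  fam["srebp"], fam["pattern"])
        ga, gd = f"GA{i + 1:04d}", f"GD{i + 1:04d}"
        gat, gdt = f"GH{i + 1:04d}_At", f"GH{i + 1:04d}_Dt"
        add_gene(ga, "A", None, "chrA1", i, fam["a_prot"], fam["ga_cds"],
                 common[0], common[1], common[2], common[3], common[4], False)
        add_gene(gd, "D", None, "chrD1", i, fam["d_prot"], fam["gd_cds"],
                 common[0], common[1], common[2], common[3], common[4], False)
        add_gene(gat, "AD", "A", "chrAt1", i, fam["a_prot"], fam["at_cds"],
                 common[0], common[1], common[2], common[3], common[4], False)
        add_gene(gdt, "AD", "D", "chrDt1", i, fam["d_prot"], fam["dt_cds"],
                 common[0], common[1], common[2], common[3], common[4], False)
        ortho_rows.append(dict(diploid_gene=ga, subgenome_gene=gat, lineage="A"))
        ortho_rows.append(dict(diploid_gene=gd, subgenome_gene=gdt, lineage="D"))
        homeo_rows.append(dict(gene_a=gat, gene_d=gdt))
    for d in dup_rows:
        chrom = "chrAt1" if d["subgenome"] == "A" else "chrDt1"
        add_gene(d["gene2"], "AD", d["subgenome"], chrom, d["family"],
                 d["protein"], d["cds"], d["domain_start"], d["category"],
                 d["basic"], d["srebp"], d["pattern"], True)

    genes = pd.DataFrame(gene_rows).set_index("gene_id")
    gff = {
        g: "##gff-version 3\n" + "\n".join(gff_entries[g]) + "\n"
        for g in gff_entries
    }

    # expression: homeolog pairs carry planted bias + correlation; duplicate
    # genes are satellites correlated with their anchor
    rng_expr_setup = np.random.default_rng(ss_expr)
    pairs = [(r["gene_a"], r["gene_d"]) for r in homeo_rows]
    bias_cats = [
        str(rng_expr_setup.choice(["Ahigh", "equal", "Dhigh"], p=list(config.bias_mix)))
        for _ in pairs
    ]
    # Divergent profiles are planted among unbiased pairs first: a planted
    # fold is only a directionally consistent per-tissue effect when the two
    # copies share their latent condition profile, so biased pairs keep the
    # conserved correlation whenever the mixes allow it.
    n_diverged = int(round((1.0 - config.homeolog_conserved_frac) * len(pairs)))
    equal_idx = [i for i, c in enumerate(bias_cats) if c == "equal"]
    other_idx = [i for i in range(len(pairs)) if bias_cats[i] != "equal"]
    rng_expr_setup.shuffle(equal_idx)
    rng_expr_setup.shuffle(other_idx)
    diverged_idx = set((equal_idx + other_idx)[:n_diverged])
    corr = [
        config.diverged_r if i in diverged_idx else config.conserved_r
        for i in range(len(pairs))
    ]
    sat = [
        (d["gene1"], d["gene2"],
         config.conserved_r
         if rng_expr_setup.random() < config.dup_conserved_frac
         else config.diverged_r)
        for d in dup_rows
    ]
    gene_lengths = {g: len(genes.at[g, "cds"]) for g in genes.index}
    counts, fpkm, expr_truth = generate_expression(
        pairs,
        None,
        corr,
        np.full(config.n_conditions, config.library_size),
        int(rng_expr_setup.integers(2**31)),
        n_conditions=config.n_conditions,
        dispersion=config.dispersion,
        bias_fold=config.bias_fold,
        gene_lengths=gene_lengths,
        base_mean=config.base_mean,
        condition_sd=config.condition_sd,
        bias_categories=bias_cats,
        satellites=sat,
        conditions=config.conditions,
    )

    homeolog_pairs = expr_truth.copy()
    dup_pairs = pd.DataFrame(
        [
            {"gene1": d["gene1"], "gene2": d["gene2"], "subgenome": d["subgenome"],
             "target_ks": d["target_ks"], "target_r": s[2]}
            for d, s in zip(dup_rows, sat)
        ],
        columns=["gene1", "gene2", "subgenome", "target_ks", "target_r"],
    )
    library_sizes = pd.Series(
        np.full(config.n_conditions, config.library_size), index=config.conditions
    )

    fam = SyntheticFamily(
        config=config,
        genes=genes,
        gff=gff,
        homeolog_pairs=homeolog_pairs,
        dup_pairs=dup_pairs,
        ortholog_pairs=pd.DataFrame(ortho_rows),
        counts=counts,
        fpkm=fpkm,
        library_sizes=library_sizes,
        expression_truth=expr_truth,
    )
    _validate_family(fam)
    return fam


def _validate_family(fam: SyntheticFamily) -> None:
    """Post-generation invariant: every CDS translates exactly to its protein."""
    for gene_id, row in fam.genes.iterrows():
        prot = str(Seq(row.cds).translate())
        if prot != row.protein:
            raise AssertionError(f"CDS/protein mismatch for {gene_id}")
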