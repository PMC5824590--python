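"""End-to-end orchestration and family-level summary statistics.

``run_pipeline`` executes every stage in order on a synthetic species trio
(generate -> domain scan -> binding classification -> intron patterns ->
Ks dating -> ortholog detection -> expression divergence and homeolog bias)
and emits per-stage TSVs, a machine-readable JSON summary and a short
human-readable report.  Percentages are computed with half-up rounding to one
decimal, the convention used in family surveys (e.g. 122/189 -> 64.6).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression as xpr
from . import ks as ksmod
from .consensus import default_model
from .domains import mean_basic_residues, scan_fasta, BindingCall
from .ks import make_protein_aligner
from .structure import IntronPattern, domain_intron_pattern, label_patterns, load_gene_models
from .synth import FamilyConfig, SyntheticFamily, generate_family

logger = logging.getLogger(__name__)

GENOMES = ("A", "D", "AD")


def proportion(count: int, total: int) -> float:
    """Percentage 100*count/total, rounded half-up to one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def reciprocal_best_hit(
    proteome1: dict[str, str],
    proteome2: dict[str, str],
    scorer=None,
) -> list[tuple[str, str]]:
    """Reciprocal-best-hit pairs between two proteomes.

    ``scorer(seq1, seq2)`` defaults to the global BLOSUM62 alignment score
    used elsewhere in the package.  Ties are broken lexicographically on the
    candidate id, which makes the result symmetric in argument order up to a
    column swap.
    """
    if not proteome1 or not proteome2:
        return []
    if scorer is None:
        aligner = make_protein_aligner()
        scorer = lambda a, b: float(aligner.score(a, b))  # noqa: E731
    ids1 = sorted(proteome1)
    ids2 = sorted(proteome2)
    scores = np.empty((len(ids1), len(ids2)))
    for i, g1 in enumerate(ids1):
        for j, g2 in enumerate(ids2):
            scores[i, j] = scorer(proteome1[g1], proteome2[g2])
    best12 = {}
    for i, g1 in enumerate(ids1):
        j = int(np.argmax(scores[i]))  # argmax returns the first (lex-lowest) tie
        best12[g1] = ids2[j]
    best21 = {}
    for j, g2 in enumerate(ids2):
        i = int(np.argmax(scores[:, j]))
        best21[g2] = ids1[i]
    return [(g1, g2) for g1, g2 in sorted(best12.items()) if best21[g2] == g1]


@dataclass
class FamilySummary:
    """Machine-readable end-of-run summary."""

    genome_totals: dict[str, int]
    category_counts: dict[str, dict[str, int]]
    mean_basic: dict[str, float]
    n_intron_patterns: int
    bias_counts: dict[str, int]
    biased_pct: float
    age_counts: dict[str, dict[str, int]]
    divergence: dict[str, dict[str, int]]
    ortholog_pairs: dict[str, int]
    recovery: dict[str, float]
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "genome_totals": self.genome_totals,
            "category_counts": self.category_counts,
            "mean_basic": self.mean_basic,
            "n_intron_patterns": self.n_intron_patterns,
            "bias_counts": self.bias_counts,
            "biased_pct": self.biased_pct,
            "age_counts": self.age_counts,
            "divergence": self.divergence,
            "ortholog_pairs": self.ortholog_pairs,
            "recovery": self.recovery,
            **self.extras,
        }


def run_pipeline(config: FamilyConfig, outdir: str | Path) -> FamilySummary:
    """Run every stage on a freshly generated synthetic trio.

    Writes the generated inputs under ``<outdir>/data`` and each stage's TSV
    plus ``summary.json`` / ``report.txt`` under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    datadir = outdir / "data"
    fam = generate_family(config)
    fam.write(datadir)
    model = default_model()

    # --- domain scan + binding classification -----------------------------
    scans: dict[str, pd.DataFrame] = {}
    for genome in GENOMES:
        df = scan_fasta(datadir / f"{genome}.proteins.fasta", model)
        df.to_csv(outdir / f"domains_{genome}.tsv", sep="\t", index=False)
        scans[genome] = df
    all_scans = pd.concat(
        [df.assign(genome=g) for g, df in scans.items()], ignore_index=True
    ).set_index("protein_id")

    # --- intron patterns ---------------------------------------------------
    pattern_rows = []
    for genome in GENOMES:
        models = load_gene_models(datadir / f"{genome}.gff3")
        df = scans[genome].set_index("protein_id")
        for gene_id, gm in models.items():
            if gene_id not in df.index:
                continue
            start = int(df.at[gene_id, "start"])
            from .domains import BHLHDomain
            dom = BHLHDomain(gene_id, start, start + 61,
                             df.at[gene_id, "aligned_domain"],
                             float(df.at[gene_id, "score"]))
            pat = domain_intron_pattern(gm, dom)
            pattern_rows.append(
                {"gene_id": gene_id, "genome": genome, "n_introns": pat.n_introns,
                 "pattern_key": pat.pattern_key,
                 "phases": ",".join(map(str, pat.phases))}
            )
    patterns_df = pd.DataFrame(pattern_rows)
    labels = label_patterns(
        [IntronPattern.from_key(k) for k in patterns_df.pattern_key]
    )
    patterns_df["label"] = patterns_df.pattern_key.map(labels)
    patterns_df.to_csv(outdir / "intron_patterns.tsv", sep="\t", index=False)

    # --- Ks dating of subgenome duplicate pairs ----------------------------
    dup_tables = {}
    for sub in ("A", "D"):
        pair_list = pd.read_csv(datadir / f"dup_pairs_{sub}.tsv", sep="\t")
        kt = ksmod.ks_table(datadir / "AD.cds.fasta", pair_list)
        kt.to_csv(outdir / f"ks_dup_{sub}.tsv", sep="\t", index=False)
        dup_tables[sub] = kt
    all_ks = pd.concat(dup_tables.values(), ignore_index=True)
    ests = [
        ksmod.KsEstimate("", "", 0, 0, 0, 0, 0, 0, row.Ks, row.Ka, True)
        for row in all_ks.itertuples()
        if np.isfinite(row.Ks)
    ]
    ksmod.ks_histogram(ests).to_csv(outdir / "ks_histogram.tsv", sep="\t", index=False)

    # --- ortholog detection (reciprocal best hit) ---------------------------
    tetra = fam.proteins("AD")
    rbh = {}
    for lineage in ("A", "D"):
        pairs = reciprocal_best_hit(fam.proteins(lineage), tetra)
        rbh[lineage] = pairs
        pd.DataFrame(pairs, columns=["diploid_gene", "subgenome_gene"]).to_csv(
            outdir / f"orthologs_{lineage}.tsv", sep="\t", index=False
        )

    # --- expression ---------------------------------------------------------
    matrix = xpr.ExpressionMatrix(fam.fpkm, fam.counts, fam.library_sizes)
    homeo = list(zip(fam.homeolog_pairs.gene_a, fam.homeolog_pairs.gene_d))
    div_homeo = xpr.divergence_table(homeo, matrix)
    div_homeo.to_csv(outdir / "divergence_homeolog.tsv", sep="\t", index=False)
    dups = list(zip(fam.dup_pairs.gene1, fam.dup_pairs.gene2))
    div_dup = xpr.divergence_table(dups, matrix)
    div_dup = div_dup.merge(
        all_ks[["gene1", "gene2", "age_class"]], on=["gene1", "gene2"], how="left"
    )
    div_dup.to_csv(outdir / "divergence_duplicates.tsv", sep="\t", index=False)

    bias_calls = xpr.bias_table(homeo, fam.counts, fam.library_sizes)
    bias_df = pd.DataFrame(
        {
            "gene_a": [c.id_a for c in bias_calls],
            "gene_d": [c.id_d for c in bias_calls],
            "overall": [c.overall for c in bias_calls],
            "n_ahigh_conditions": [
                sum(v == "Ahigh" for v in c.per_condition.values()) for c in bias_calls
            ],
            "n_dhigh_conditions": [
                sum(v == "Dhigh" for v in c.per_condition.values()) for c in bias_calls
            ],
            "min_q": [min(c.q_values.values()) if c.q_values else float("nan")
                      for c in bias_calls],
        }
    )
    bias_df.to_csv(outdir / "bias_homeolog.tsv", sep="\t", index=False)

    # --- summary ------------------------------------------------------------
    summary = _summarise(fam, scans, patterns_df, labels, all_ks,
                         div_homeo, div_dup, bias_df, rbh)
    (outdir / "summary.json").write_text(json.dumps(summary.to_dict(), indent=2) + "\n")
    (outdir / "report.txt").write_text(_render_report(summary))
    return summary


def _summarise(fam: SyntheticFamily, scans, patterns_df, labels, all_ks,
               div_homeo, div_dup, bias_df, rbh) -> FamilySummary:
    genome_totals = {g: int((fam.genes.genome == g).sum()) for g in GENOMES}
    category_counts = {}
    mean_basic = {}
    for g, df in scans.items():
        counts = df.category.value_counts().to_dict()
        counts["Total"] = int(len(df))
        category_counts[g] = {k: int(v) for k, v in counts.items()}
        calls = [BindingCall(r.category, int(r.basic_count), bool(r.srebp_like))
                 for r in df.itertuples()]
        mean_basic[g] = mean_basic_residues(calls) if calls else float("nan")

    n_pairs = len(bias_df)
    bias_counts = bias_df.overall.value_counts().to_dict()
    bias_counts = {k: int(bias_counts.get(k, 0))
                   for k in ("Ahigh", "equal", "Dhigh", "mixed", "not_tested")}
    n_biased = bias_counts["Ahigh"] + bias_counts["Dhigh"]
    biased_pct = proportion(n_biased, n_pairs) if n_pairs else float("nan")

    age_counts = {}
    for sub in ("A", "D"):
        sel = all_ks[all_ks.gene1.isin(
            fam.dup_pairs[fam.dup_pairs.subgenome == sub].gene1
        ) & all_ks.gene2.isin(
            fam.dup_pairs[fam.dup_pairs.subgenome == sub].gene2
        )]
        age_counts[sub] = {k: int(v) for k, v in sel.age_class.value_counts().items()}

    divergence = {
        "homeolog": {k: int(v) for k, v in div_homeo.call.value_counts().items()},
        "duplicates": {k: int(v) for k, v in div_dup.call.value_counts().items()},
    }

    # recovery against planted truth
    truth = fam.ground_truth
    scan_all = pd.concat(scans.values(), ignore_index=True).set_index("protein_id")
    joined = truth.genes.join(scan_all[["category", "basic_count"]],
                              rsuffix="_called", how="left")
    detected = joined.category_called.notna()
    cat_ok = (joined.category == joined.category_called) & detected
    pat_truth = truth.genes.intron_key
    pat_called = patterns_df.set_index("gene_id").pattern_key
    pat_ok = pat_truth.eq(pat_called.reindex(pat_truth.index))
    bias_truth = fam.homeolog_pairs.set_index(["gene_a", "gene_d"]).bias
    bias_called = bias_df.set_index(["gene_a", "gene_d"]).overall
    planted_biased = bias_truth[bias_truth.isin(["Ahigh", "Dhigh"])]
    bias_ok = (bias_called.reindex(planted_biased.index) == planted_biased)
    ks_cmp = all_ks.merge(fam.dup_pairs, on=["gene1", "gene2"])
    rel_err = (ks_cmp.Ks - ks_cmp.target_ks).abs() / ks_cmp.target_ks

    planted_orth = {
        lineage: set(
            map(tuple, truth.ortholog_pairs[
                truth.ortholog_pairs.lineage == lineage
            ][["diploid_gene", "subgenome_gene"]].itertuples(index=False))
        )
        for lineage in ("A", "D")
    }
    rbh_recovery = {
        lineage: len(planted_orth[lineage] & set(rbh[lineage])) / len(planted_orth[lineage])
        for lineage in ("A", "D")
    }

    recovery = {
        "domain_detection_pct": proportion(int(detected.sum()), len(joined)),
        "binding_category_pct": proportion(int(cat_ok.sum()), len(joined)),
        "intron_pattern_pct": proportion(int(pat_ok.sum()), len(pat_ok)),
        "planted_bias_pct": (
            proportion(int(bias_ok.sum()), len(bias_ok)) if len(bias_ok) else float("nan")
        ),
        "ks_mean_rel_error_pct": round(float(rel_err.mean()) * 100.0, 2),
        "ortholog_rbh_pct_A": proportion(
            int(len(planted_orth["A"] & set(rbh["A"]))), len(planted_orth["A"])),
        "ortholog_rbh_pct_D": proportion(
            int(len(planted_orth["D"] & set(rbh["D"]))), len(planted_orth["D"])),
    }
    del rbh_recovery

    return FamilySummary(
        genome_totals=genome_totals,
        category_counts=category_counts,
        mean_basic=mean_basic,
        n_intron_patterns=len(labels),
        bias_counts=bias_counts,
        biased_pct=biased_pct,
        age_counts=age_counts,
        divergence=divergence,
        ortholog_pairs={lineage: len(rbh[lineage]) for lineage in ("A", "D")},
        recovery=recovery,
    )


def _render_report(summary: FamilySummary) -> str:
    lines = ["Synthetic bHLH family pipeline report", "=" * 38, ""]
    lines.append("Predicted DNA-binding categories per genome:")
    for g, counts in summary.category_counts.items():
        parts = ", ".join(f"{k}: {v}" for k, v in sorted(counts.items()))
        lines.append(f"  {g}: {parts}")
    lines.append("")
    lines.append(f"Mean basic residues (N-terminal 17 positions): "
                 + ", ".join(f"{g}={v}" for g, v in summary.mean_basic.items()))
    lines.append(f"Distinct intron patterns: {summary.n_intron_patterns}")
    lines.append("")
    lines.append(f"Homeolog bias: {summary.bias_counts} "
                 f"(biased: {summary.biased_pct}%)")
    lines.append(f"Duplicate age classes: {summary.age_counts}")
    lines.append(f"Expression divergence: {summary.divergence}")
    lines.append(f"Reciprocal-best-hit ortholog pairs: {summary.ortholog_pairs}")
    lines.append("")
    lines.append("Recovery of planted truth:")
    for k, v in summary.recovery.items():
        lines.append(f"  {k}: {v}")
    return "\n".join(lines) + "\n"
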