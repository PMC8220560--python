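# hohla — hierarchically organized haplotype analysis of HLA-DRB1

HLA-DRB1 is among the most polymorphic genes in the genome, and its
subtypes can be risk-increasing, neutral, or protective for the same
autoimmune disease — HLA-DR4 and type 1 diabetes being the canonical
puzzle.  Allele-level association tables answer *which alleles* but not
*why*.  `hohla` is a reusable, tested pipeline for peeling that nomenclature
apart down to amino acids:

1. **Organize** alleles into a hierarchy by protein-sequence similarity
   (normalized Hamming distance on the aligned β-chain, UPGMA linkage), and
   read clusters such as "DR4" off the tree.
2. **Screen** residues within a cluster: drop positions that are
   monomorphic, vary only on rare alleles (< 3 chromosome copies), or sit
   in complete LD with an earlier position.
3. **Test** the surviving residues and their joint motifs (e.g. "KAG" at
   β71/β74/β86) in a case-control sample using a *virtual-reference odds
   ratio* — the case chromosome frequency of a category over its control
   frequency, OR(c) = f₁(c)/f₀(c), so no reference category is elected —
   with significance from the score statistic Z of the category's
   chromosome dosage under a null logistic fit, and SE = log(OR)/Z when a
   standard error is needed.  Extend to DRB1-motif × DQA1 × DQB1
   haplotypes via EM phase estimation.
4. **Validate** motifs in an independent birth cohort: derive
   seroconversion endpoints (overall, double, and antibody-specific) from
   longitudinal GADA/IAA/IA-2A panels, then fit Kaplan-Meier incidence,
   log-rank contrasts, one-vs-rest and reference-based Cox models, and a
   genotype dose-response model (0/1/2 motif copies), with the
   Grambsch-Therneau proportionality diagnostic on every fit.

A synthetic-data module generates allele catalogs, case-control samples
(logistic disease model, rejection-sampled by arm), and cohort antibody
panels (Weibull proportional hazards seen through noisy scheduled visits)
with the latent truth retained for oracle testing.  It ships a synthetic
DR4 fixture catalog pinning the documented cluster structure: seven motifs
at (β71, β74, β86), KAG uniquely on DRB1\*04:01, RAV on 04:04/04:10, REG on
04:07, β37 near-monomorphic, β67/β70 in complete LD.

The intended users are statistical geneticists fine-mapping HLA (or any
hyper-polymorphic locus) who want the full allele→residue→motif→haplotype
→survival chain as composable library functions plus a thin CLI.

## Worked example

```python
import importlib.resources
from hohla import (load_alignment, pairwise_distances, build_tree,
                   extract_cluster, parse_allele_name, positions_from_indices,
                   screen_residues, motif_assoc_table)
from hohla.assoc import assoc_frame
from hohla.simulate import dr4_fixture_subjects

data = importlib.resources.files("hohla") / "data"
catalog = load_alignment(data / "dr4_synthetic_alignment.fasta",
                         data / "dr4_synthetic_positions.tsv")
tree = build_tree(pairwise_distances(catalog))
cluster = extract_cluster(
    tree, [parse_allele_name("DRB1*04:01"), parse_allele_name("DRB1*04:03")],
    label="DR4")
print("DR4 cluster:", ", ".join(a.canonical for a in cluster.sorted_members()))

subjects = dr4_fixture_subjects()          # deterministic 38-case/41-control roster
screen = screen_residues(catalog, cluster, subjects,
                         positions_from_indices([37, 57, 67, 70, 71, 74, 86]))
for pos, status in screen.status.items():
    print(f"{pos.label}: {status}")

table = motif_assoc_table(subjects, catalog,
                          positions_from_indices([71, 74, 86]), cluster)
print(assoc_frame(table).round(3).to_string(index=False))
```

This prints:

```
DR4 cluster: DRB1*04:01, DRB1*04:02, DRB1*04:03, DRB1*04:04, DRB1*04:05, DRB1*04:06, DRB1*04:07, DRB1*04:08, DRB1*04:10, DRB1*04:13
β37: near_monomorphic
β57: kept
β67: kept
β70: collapsed_LD
β71: kept
β74: kept
β86: kept
category  n_case  f_case  n_ctrl  f_ctrl    OR      Z     SE     p                          flags
     EAV       3   0.067       2   0.071 0.933  0.114 -0.605 0.909
     KAG      20   0.444       6   0.214 2.074  2.564  0.285 0.010
     KAV       1   0.022       0   0.000   NaN  0.865    NaN 0.387 rare;or_undefined;se_undefined
     RAG       9   0.200       5   0.179 1.120  0.490  0.231 0.624
     RAV      10   0.222       7   0.250 0.889  0.121 -0.975 0.904
     REG       1   0.022       4   0.143 0.156 -1.768  1.052 0.077
     REV       1   0.022       4   0.143 0.156 -1.768  1.052 0.077
```

Reading it: the ten DR4 subtypes fall in one clade; β37 varies only on the
rare 04:06 and is set aside, β70 is determined by β67 (complete LD), and
five residues survive screening.  Among DR4 chromosomes the "KAG" motif is
carried by 44.4% of case chromosomes versus 21.4% of control chromosomes
(virtual-reference OR 2.07, score Z = 2.56, p = 0.010 on this small demo
roster), the single "KAV" chromosome is flagged rare with an undefined OR,
and the β74E motifs (REG, REV) trend protective.

The same stages are available from the shell — `hohla simulate`, `hohla
tree`, `hohla screen`, `hohla cc-assoc`, `hohla motif`, `hohla dq`, `hohla
sero`, `hohla cox`, `hohla dose` — each reading a YAML config and writing
deterministic TSV/Newick outputs plus a log (`hohla --help`).

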