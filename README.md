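# ppprofiler

Partial phylogenetic profiling for comparative genomics: rank every gene in
a genome by how significantly its homolog distribution co-occurs with a
binary taxonomic trait profile, while simultaneously optimizing the
boundary of each gene's protein family.

## The problem

Phylogenetic profiling links proteins that "travel together" through
speciation, gene loss and lateral transfer: if two protein families occur
in the same set of genomes, they likely cooperate in one cellular system.
The classic approach compares two *pre-built* family profiles, but family
boundaries inside large homologous superfamilies are exactly what is
uncertain — a fixed BLAST E-value cutoff misdefines families whose "right"
cutoff can vary over a hundred orders of magnitude.

Partial phylogenetic profiling (PPP) sidesteps pre-built families. For a
gene *G* with a ranked homolog list (BLAST or HMMER hits, one best hit per
taxon), descend the list and, after each of the first *j* distinct taxa
that appear in the query profile, count how many, *h<sub>j</sub>*, are
profile positives (T1). The agreement at depth *j* is the upper binomial
tail

&nbsp;&nbsp;&nbsp;&nbsp;p<sub>j</sub> = P(X ≥ h<sub>j</sub>),&nbsp;
X ~ Binomial(j, p),

where the prior *p* defaults to |T1| / (|T1| + |T0|) and can be overridden:
raising *p* raises the penalty per mismatch and favours rare families with
an "only if" relationship to the profile. The gene's score is
−log10 p\* with p\* = min<sub>j</sub> p<sub>j</sub> — the depth where the
growing family agrees best with the profile. That depth *is* a proposed
family boundary, and the E-values flanking it ("last true" / "first
false") are ready-made cutoffs for building HMMs.

Double PPP (DPPP) bootstraps the query profile itself from a single seed
protein: profiles are built from successive depths of the seed's hit list
and each gene keeps its best PPP score over all sampled depths.

## Worked example

Everything runs on generated data — no databases to download:

```sh
ppprofiler synth --seed 1 --out demo            # 100 genomes, one planted
                                                # 10-gene system in 15 carriers
ppprofiler ppp --profile demo/profile_sys0.tsv \
    --blast demo/blast_1001.tsv --id2tax demo/id2tax.tsv -o demo/out.tsv
head -12 demo/out.tsv | grep -v '^#'
```

```
sys0m0@1001	12.36	4.37823e-13	15	15	2.582e-26	1.781e-07
sys0m1@1001	12.36	4.37823e-13	15	15	9.034e-22	1.321e-08
...
bg1@1001	2.47	0.00340604	3	3	1.112e-116	1.672e-116
```

The ten planted members occupy the top ten ranks. Each reaches its optimum
at depth j\* = 15 with h\* = 15 matches — all fifteen carrier genomes and
nothing else — so the score is the closed form
15 · (−log10 0.15) = 12.36. Columns 6–7 are the E-values flanking the
chosen family boundary: members' last in-family hit sits around 1e-21 or
better while the first outside hit is around 1e-8, the gap where a family
cutoff belongs. The best background family manages only 2.47.

The depth sweep from a single seed protein:

```sh
ppprofiler dppp --query-gene sys0m0@1001 --blast demo/blast_1001.tsv \
    --id2tax demo/id2tax.tsv --universe demo/universe.tsv -o demo/dppp.tsv
```

ranks the other nine members immediately below the seed, each peaking at
the sampled depth nearest the true carrier count.

The library mirrors the CLI: `score_genome`, `score_gene`, `dppp_sweep`,
`optimal_hmm_cutoff`, profile algebra (`combine`, `mask`,
`profile_from_taxon`, `profile_from_hits`) and the taxdump-backed rank
collapsing are all importable from `ppprofiler`.

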