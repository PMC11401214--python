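# nanomatch

Nanobody (VHH) candidate discovery from high-throughput amplicon
sequencing and shotgun mass-spectrometry peptide evidence.

Camelid serum contains heavy-chain-only antibodies (HCAb) whose single
variable domain (VHH) makes an excellent affinity reagent when expressed
alone as a nanobody. To identify the VHHs that actually bind an antigen
of interest, antigen-enriched HCAb is digested and analyzed by tandem
MS, while in parallel the animal's VHH repertoire is amplified from
lymphocyte cDNA and sequenced. `nanomatch` performs the computational
arm of that workflow:

1. **build-db** — merge 2×300-class paired-end amplicon reads on their
   overlap, locate the leader forward primer and long-/short-hinge
   reverse primers with a fractional mismatch budget
   (`ceil(0.2 × 23) = 5` mismatches for the 23-base leader primer),
   classify each amplicon's hinge (long hinge → IgG2, short hinge →
   IgG3), translate the ORF between the primers, and collapse identical
   proteins while counting read support.
2. **annotate** — locate FR1–FR4/CDR1–3 boundaries from the conserved
   anchor landmarks (Cys-23, Trp-41, Cys-104 in its Y-x-C context, and
   the FR4 W-G-x-G motif), pin an IMGT-style position map to them, and
   flag the conventional-VH hallmark GLEW at IMGT 49–52.
3. **digest / cleavage-hist** — in silico digestion under the simple
   Expasy-style rules for trypsin and chymotrypsin (high and low
   specificity), unique-peptide FASTA lists, and the cleavage-event
   histogram by IMGT position.
4. **rank** — map MS-identified peptides back onto the database
   (leucine/isoleucine treated as identical), score every sequence by
   CDR-weighted coverage (default per-residue weights FR=1, CDR1=3,
   CDR2=3, CDR3=10), group sequences into CDR3 clonotypes, rank groups
   by their top-scoring member and members by read count, and compute
   each peptide's **uniqueness score**

   ```
   uniqueness = 100 × |{s ∈ CDR3 group : s contains peptide}|
                     / |{s ∈ database  : s contains peptide}|
   ```

   — the probability the peptide originated from that clonotype.
   Selection requires at least one peptide with uniqueness
   strictly above 80, no cross-antigen peptide evidence (nonspecific
   binding), and no GLEW hallmark (VH contamination).
5. **simulate** — a fully seeded synthetic-data generator (repertoire,
   reads, noisy dual-protease peptide observations, unrelated-antigen
   decoy sample) so the entire pipeline is testable with known ground
   truth and no external data.

## Worked example

Generate a synthetic experiment (100 clones, 3 binder clones, 4000 read
pairs) and run the whole pipeline on it:

```
$ cat config.yaml
simulate:
  n_clones: 100
  n_binders: 3
  n_read_pairs: 4000

$ nanomatch --log-level ERROR run-all --config config.yaml --seed 42 --outdir run
2166 proteins, 446 groups, 276 selected -> run
```

The run directory contains the protein database (`database.fasta`, with
`count=` and `hinge=` encoded in headers), the ranked candidate report
(`report.tsv` / `report.json`), the spectral-review evidence table
(`evidence.json`) and a reproducibility manifest. The top of the report:

```
top 3 groups:
  grp_827be80839  cdr3=EPHEVYNTESEGGPA      score=100.0  reads=348  top_member_best_uniqueness=100  selected=True
  grp_2f908f9395  cdr3=KFFLSMLGQFTNPPFHHVD  score=100.0  reads=61   top_member_best_uniqueness=100  selected=True
  grp_2a264954e0  cdr3=LEQAV                score=100.0  reads=38   top_member_best_uniqueness=100  selected=True
```

These three CDR3 clonotypes are exactly the three binder clones the
simulation spiked in: each reaches full CDR-weighted coverage, is
supported by dozens to hundreds of sequencing reads, and carries at
least one clonotype-unique (uniqueness 100) peptide. The 2166 database
entries are dominated by singleton sequencing-error variants of the 100
true clones; those collapse into their parent clonotype when the error
is outside CDR3 and are out-competed on score and read count otherwise.
The `276 selected` counts every group member passing the per-sequence
selection rule — in practice the top-count member of each shortlisted
group is the candidate taken forward to synthesis.

The same stages are available piecewise (`nanomatch simulate`,
`build-db`, `survey`, `annotate`, `digest`, `cleavage-hist`, `rank`),
and everything is importable as a library (`nanomatch.amplicon`,
`.annotate`, `.digest`, `.match_score`, `.simulate`, `.seqio`).

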