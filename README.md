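# evescreen

Database-integrated genome screening for **endogenous viral elements (EVEs)**
— virus-derived DNA that integrated into a host germline in the past and is
now inherited as a host allele. EVEs (endogenous retroviruses, endogenous
bornavirus/filovirus/circovirus/parvovirus/hepadnavirus elements, ...) are
sporadic, often highly degraded, and invisible to routine genome annotation.
Finding and interpreting them requires screening many whole-genome assemblies
with sensitive similarity searches *and* keeping the flood of hits organized
well enough to filter contaminants, resolve orthology, and compute
evolutionary quantities.

`evescreen` is a toolkit for paleovirologists and comparative genomicists
that couples the two halves:

* **Screening.** Every probe × genome-file search is tracked in an embedded
  SQL project database. Screening is incremental and resumable: interrupt a
  run, add genomes or probes, restart — only outstanding searches execute.
  Raw local-alignment hits are *defragmented* (hits on one contig and strand
  that overlap or lie within a configurable range are merged by transitive
  closure into one locus), the locus sequence is extracted, and each locus is
  *classified* by its best match in a curated reference sequence library
  (RSL), recording taxon, gene, bitscore, e-value and identity. Updating the
  RSL and reclassifying (optionally under an SQL constraint) is the central
  curation move — it is how cross-matching host genes, transposons and
  retroviral glycoproteins are progressively recognized.
* **Analytics.** Contamination flags (≥98% identity to a known virus, absent
  genomic flanks, intact coding — together: putatively exogenous), stop-codon
  and frameshift counting against a reference protein, six-frame ORF
  scanning, ortholog/paralog resolution (one ortholog group = one germline
  incorporation event), minimum insertion ages from a time-calibrated host
  tree, and germline infiltration rates

  ```
  rate = n_events / branch_length_sampled        [events per MY]
  ```

  where the denominator is the branch length (in millions of years) of the
  minimal subtree spanning the sampled species of a host class. Standardized
  locus identifiers of the form `<classifier>-<virus_taxon>.<n>-<distribution>`
  (e.g. `EBLL-Cultervirus.29-EptFus`) round-trip through a parser/formatter.

Search backends are pluggable: NCBI BLAST+ (`tblastn`/`blastn`) when
installed, and a hermetic in-process engine (Smith–Waterman over all six
translation frames, BLOSUM62, bitscores via `b = (λS − ln K)/ln 2`) that
needs no external tools. Bitscore is the filtering currency throughout, with
a counting cutoff of 60 bits and a conservative high-confidence cutoff of 90.

A deterministic synthetic-fixture generator builds miniature study systems —
background genomes with implanted, degraded viral elements plus ground-truth
tables — so the entire pipeline is testable without downloading a single
assembly.

## Worked example

Generate the standard synthetic study system (six species, five virus
families, 30 implants at 15% substitution degradation including one
two-species orthologous insertion, plus one virus/transposon chimera), then
screen it:

```bash
$ evescreen fixtures make --seed 42 -o demo && cd demo
$ evescreen screen -c control.yaml
searches run: 36
hits found: 37
loci created: 31
loci updated: 0
```

36 searches (6 probes × 6 genome files) produced 37 raw hits that merged to
31 loci — every implant recovered as a single locus. Summarize by assigned
taxon (the chimeric transposon implant is claimed by the RSL's transposon
entry, not the virus — the cross-match filter working as intended):

```bash
$ evescreen db-import -c control.yaml --name host_taxonomy --key species_name host_taxonomy.tsv
$ evescreen summarize -c control.yaml
assigned_taxon  total   per_genome_average
Bornaviridae    8       1.33
Circoviridae    6       1.0
Filoviridae     6       1.0
Hepadnaviridae  5       0.83
Parvoviridae    5       0.83
Teratorn        1       0.17
```

Resolve orthology, date shared insertions, and estimate infiltration rates
against the bundled time tree:

```bash
$ evescreen ages -c control.yaml --tree timetree.nwk | head -2
group_id        virus_taxon  n_members  host_species        min_age_my
Bornaviridae.1  Bornaviridae 2          bat_alpha,bat_beta  25.0
$ evescreen rates -c control.yaml --tree timetree.nwk
host_class  virus_family    n_events  branch_length_my  rate_per_my
Mammalia    Bornaviridae    5         217.0             0.02304
Mammalia    Circoviridae    2         217.0             0.00922
Mammalia    Filoviridae     5         217.0             0.02304
Mammalia    Hepadnaviridae  1         217.0             0.00461
Mammalia    Parvoviridae    2         217.0             0.00922
```

The 30 viral implants resolve to 29 incorporation events (the bornavirus
insertion shared by the two bats counts once); its minimum age, 25 MY, is
the bats' divergence time in the fixture tree; the mammalian bornavirus
infiltration rate is 5 events over the 217 MY of mammal branch length
sampled by the tree.

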