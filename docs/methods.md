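# Methods

## Editor model

A prime editor is reduced to an `EditorProfile`: an IUPAC PAM pattern 3′ of
a 20-nt protospacer (Cas9 geometry), a canonical nick offset N (the
non-target-strand nick sits N protospacer nucleotides upstream of the PAM),
and an editable window (lo, hi) of nick-relative positions. Internally all
coordinates are 0-based with half-open intervals; a nick is a *gap index* g
("between base g−1 and base g"), which makes insertion-point arithmetic
unambiguous. User-facing tables are 1-based inclusive; BED output is
0-based half-open, with nicks as zero-length features.

Relative-position sign convention: +k is the k-th base on the PAM-proximal
side of the nick, −k the k-th base on the PAM-distal side, and position 0
does not exist. The empirical window descriptions this models ("−6 to +3
around the nick") do not define a sign, so the convention is fixed here
once and used everywhere, including `relative_edit_position` in designs.

Built-in profiles: `SpPE` (NGG, N=3, window −1..+3), `FnPE` (NGG, N=6,
window −6..+3), `RHA-FnPE` (YG, N=6, window −6..+3). Two deliberate
simplifications:

* Nicking of these enzymes is heterogeneous in vitro (3–4 bp upstream of
  the PAM for SpCas9, 6–8 bp for FnCas9 on the non-target strand; 3 bp on
  the target strand for both). The profiles collapse this to the canonical
  design offsets 3 and 6 — the offsets used when constructing pegRNAs —
  and leave the ranges expressible through custom profiles. No window
  union over the 6–8 range is taken.
* The relaxed-PAM variant differs only in its PAM pattern (YG, Y={C,T});
  no attempt is made to model the underlying protein engineering. Its
  protospacer is kept at 20 nt like the NGG profiles.

Profile validation enforces 1 ≤ N ≤ 20, lo ≤ −1 < +1 ≤ hi, hi ≤ N (no
editing inside the PAM) and N − lo ≤ 20 (window inside the protospacer).

## Site scanning

`scan_contig` finds every plus-strand occurrence of the PAM pattern and
every plus-strand occurrence of its reverse complement (a minus-strand
PAM: CCN for NGG, CR for YG) with a regex lookahead so overlapping
occurrences are all reported. A site is dropped when its protospacer, PAM
or window leaves the contig or overlaps an ambiguous base (N): ambiguous
template cannot be designed against, and windows are never clipped.
Soft-masking (lowercase) is ignored. `scan_genome` applies a contig
exclusion set with dialect-insensitive matching (Y/chrY; MT/chrM/chrMT),
warning — not failing — on excluded names absent from the FASTA.

## Coverage statistic

A variant is *targetable* for an editor iff its position lies in the
editable window of ≥ 1 site of that editor, on either strand — an
installed edit rewrites both strands, and both-strand windows are the
natural complement of scanning reverse-complement PAMs. Each variant
counts once however many sites cover it:

covered ratio (%) = targetable / total × 100, uncovered = 100 − covered.

Zero variants after filtering is an error, never a 0/0 ratio. Variant
identity defaults to the full record (contig, pos, ref, alt) — the same
position with two alt alleles is two SNPs — with position-level
deduplication available (`dedup="position"`); the two policies give equal
ratios only when multiallelic records are absent. Only single-nucleotide
substitutions participate; indels and MNVs are counted as skipped.
Multiallelic VCF rows are split per-alt before filtering. The significance
filter is a plain case-insensitive substring test against a significance
column or the CLNSIG INFO field; no ontology handling. Variants must
already be on the scanned assembly's coordinates (no liftover). Because
editors' windows nest at shared PAM sites, widening a window or taking a
union of editors can only grow the targetable set; both monotonicities are
asserted in the test suite.

An optional external check — running `coverage` with the `RHA-FnPE`
profile on a current ClinVar pathogenic-SNV export against GRCh38,
excluding Y and MT — reproduces the kind of genome-wide covered-ratio
figure this statistic was built for (a YG PAM covers a large majority of
pathogenic SNVs). It needs several GB of downloads and drifts with the
ClinVar snapshot, so it is documented here rather than tested; the report
always emits both per-editor and union coverage because a headline figure
of this kind can refer to either.

## pegRNA design

The designer works in a local frame where the site lies on the plus strand
(minus-strand sites are handled by mirroring the contig, p → L−1−p, and
complementing the edit). With nick gap g:

* PBS = reverse complement of the L_pbs bases immediately 5′ of the nick
  on the nicked strand, so reverse_complement(PBS) is a protospacer
  substring ending at the nick; L_pbs is capped at 20 − N.
* RTT = reverse complement of the *edited* sequence over [g, g + L_rtt).
  Correctness is defined by the round-trip identity: writing
  reverse_complement(RTT) onto the nicked strand 3′ of the nick must
  reproduce the edited allele exactly. The test suite and acceptance
  script verify this against an independent splicing oracle on 500 random
  (locus, edit, L_pbs, L_rtt) draws.
* L_rtt must cover the edit plus ≥ 1 nt of downstream homology
  (`RttTooShortError` carries the minimum feasible length); the default is
  edit end + 7 nt homology. Defaults L_pbs 13, sweep bounds PBS 8–17 and
  RTT 10–34, all configurable — published pegRNA designs vary these
  per-locus and no single value is privileged.

Because reverse transcription extends the 3′ end created by the nick, the
RTT can only rewrite sequence on the PAM-proximal side of the nick. An
in-window edit 5′ of the nick (negative relative position) therefore has
no canonical-nick design and raises `EditUpstreamOfNickError`. Such
positions are still *covered* in the coverage module: the editable windows
are empirical, and distal positions are reached in cells through the
nickase's cleavage heterogeneity, which the designer deliberately does not
model. Candidate search (`candidate_sites_for_edit`) is window-membership
only and ranks nick-proximal first; an empty result reports the nearest
PAM and its distance.

PE3 nicking guides are opposite-strand sites of a chosen profile whose
nick-to-nick distance lies in a configurable range (default 40–100 bp),
sorted by |distance|. PE4 assembly concatenates
spacer+scaffold+RTT+PBS | Csy4 site | ngRNA spacer+scaffold with a tiling
annotation table. The scaffold default is the generic single-guide
scaffold and the Csy4 site default is the canonical 28-nt hairpin; both
are placeholders to be overridden for a specific vector system, and linker
variants are expressed by substituting the scaffold string. Sequences are
emitted as DNA; `rna=True` transliterates. Spacers not beginning with G
additionally report a G-prepended variant for U6 expression; the original
is never silently altered.

## Outcome quantification

The precise/indel/WT classification rules are conventions of this package
(amplicon pipelines differ in their fine print), chosen to depend on
thresholds rather than alignment scores:

* **precise** — gap-free alignment to the edited amplicon with
  ≤ `max_mismatch` (default 5) mismatches AND exact identity over the edit
  locus ± `flank` (default 5) nt;
* **wt** — the symmetric test against the WT amplicon;
* **indel** — otherwise, if the optimal alignment to either reference has
  a gap intersecting the edit locus ± flank;
* **ambiguous** — everything else: empty reads, reads not covering the
  locus, reads exceeding every tolerance.

Alignment is global affine (match 2, mismatch −3, gap open −5, extend −1)
with free end overhangs so partial reads align as an infix
(Bio.Align.PairwiseAligner). For equal-length read/reference pairs these
penalties make the optimal alignment gap-free, so a direct mismatch count
is used as an exact fast path. Reads are evaluated in both orientations;
labels are deterministic and orientation-invariant. Percentages are
reported over classified (non-ambiguous) reads. One consequence of the
"either reference" indel rule: a WT-derived read with more than
`max_mismatch` errors is usually labelled indel (via its gapped alignment
to the edited reference) rather than ambiguous; at the default tolerance
and realistic error rates such reads are vanishingly rare.

Run-off nick calling anchors each read by exact match of its first 15 nt
(failures count as unmapped), extends the longest reference-consistent
prefix tolerating 1 mismatch, then trims up to `max_trim_a` (default 1,
matching single-A polymerase tailing) terminal A's that do not match the
reference. The prefix end is the cut gap; modal offsets are histogram
maxima in bp upstream of the PAM start. An untemplated A over a reference
position that *is* A is inherently indistinguishable from template — an
ambiguity of the assay itself — so synthetic fixtures place non-A bases at
candidate cut gaps to keep ground truth exact.

## Synthetic data

Generators are pure functions of (parameters, seed) via
`numpy.random.default_rng`. Genomes are i.i.d. bases at a chosen GC
(default 0.41, the human average). Planting writes concrete PAM bases
(minus-strand plants appear as the reverse-complement pattern) without
overlapping previously written PAMs; incidental extra PAM occurrences can
arise, so truth guarantees planted ⊆ found, and variant placement uses a
post-plant scan. Variant tables place exactly round(n·f) SNVs inside the
scanned window union and the rest strictly outside, so
`compute_coverage` must return 100·f exactly — an integer-exact, not
statistical, check. Amplicon read sets draw from three allele classes
(indel alleles are random 1–3 nt insertions/deletions at the edit locus,
resampled if they coincide with WT or the precise allele) with uniform
substitution error and constant Q40 qualities; run-off reads are reference
prefixes ending at sampled cut gaps with optional terminal A. Class and
offset counts use exact largest-remainder partitioning by default
(multinomial sampling is available), which removes sampling noise from
planted-truth tests.

What the generators do **not** model: sequencing-quality profiles, PCR
bias and chimeras, paired-end structure, repeat structure or realistic
base composition of genomes, and any sequence-dependent editing-efficiency
biology. Tests passing on this synthetic data show the *computational*
pipeline is correct against planted truth; they say nothing about wet-lab
editing efficiencies, which are biological outcomes outside this package's
scope.

## Problem sizes and numerics

The test suite and acceptance script use desk-scale inputs chosen to keep
checks exact and fast while exercising every code path: 200 random genomes
≤ 2 kb for scanner/oracle equivalence, 100-SNV tables on ~5 kb planted
genomes for coverage, 500 random designs for the round-trip property, 20
read sets of 10,000 reads (0.1 %/base error) for quantifier recovery —
the ±1.5-percentage-point band is ~3 binomial standard deviations at
n = 10,000, accommodating the small additional variance from
classification of error-bearing reads — and 120-read run-off libraries.
Determinism: every stochastic step takes an explicit seed; CLI runs write
run metadata (version, parameters, input checksums) alongside outputs, and
outputs are written atomically.

## Known limitations

* No off-target search, mismatch-tolerant scanning or efficiency
  prediction; candidate ranking is purely geometric (nick proximity).
* No liftover; variants and genome must share an assembly.
* The designer refuses edits 5′ of the nick rather than modelling distal
  nick heterogeneity (above).
* Amplicon classification assumes pre-processed single-end (or pre-merged)
  reads; no adapter trimming, quality filtering or mate merging.
* Editor profiles treat the protospacer length as fixed per profile
  (default 20 nt) and assume Cas9 geometry (PAM 3′ of the protospacer).
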