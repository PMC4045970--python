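# Methods

This package reimplements, as a tested pipeline over synthetic data, the
analysis chain of a ddRAD linkage-mapping study in an outbred F1
(cross-pollinator) design: marker discovery against three reference
dialects, CP map construction, reference-strategy evaluation,
genetic-map-guided scaffold anchoring, and a within-genome
heterozygosity scan.  This note records the models, the parameters that
matter, and the choices made where the design was genuinely open.

## The cross and its genetic model

The design is a pseudo-testcross: an F1 family from a near-homozygous
maternal parent (the individual behind the reference assembly) and a
heterozygous paternal parent.  Loci heterozygous in exactly one parent
segregate 1:1 (`nn x np` when paternal, `lm x ll` when maternal); loci
heterozygous in both segregate 1:2:1 (`hk x hk`).  Because the maternal
genome carries roughly twelve-fold fewer heterozygous sites (0.03% vs
0.37% per base by default), almost all informative markers are paternal
testcross markers and the paternal map is the dense one — the central
asymmetry of the study design, which the simulator reproduces.

Crossovers are drawn as a Poisson process along each scaffold with no
interference: expected crossovers per gamete = length(Mb) x cM/Mb / 100.
Under this model the truth recombinant fraction between two markers d cM
apart is Haldane's (1 - e^(-2d/100))/2; for d = 10 cM this is 0.0906,
and the simulator's truth checks use that conversion.  The *estimation*
side uses Kosambi's map function, d = 25 ln((1+2r)/(1-2r)), because that
is the convention of the mapping protocol being modelled.  The two map
functions differ by about 1% at 2.5 cM spacings, far below the sampling
noise of n = 51 progeny, so the mismatch between the simulator's truth
model and the estimator's map function is immaterial at the spacings
used here; it is a deliberate asymmetry, not an oversight.

## The synthetic data generator

The generator emulates, at desk scale, the statistical structure the
analysis assumes.  Defaults (the "study conditions"):

| parameter | default | why |
|---|---|---|
| progeny | 51 | family size of the emulated design |
| maternal / paternal het rate | 0.0003 / 0.0037 per base | the 0.03% / 0.37% contrast |
| SNP : indel mix | 0.9 : 0.1, indels 1-2 bp | matches the marker model (SNPs or 1-2 bp indels) |
| enzymes | NsiI (ATGCA/T) + MseI (T/TAA) | the ddRAD pair |
| size selection | 200-500 bp | gel cut of the protocol |
| read length / tag | 100 bp, 92 bp after barcode | sequencing design |
| barcodes | 4-8 bp, prefix-free | inline barcode design |
| per-progeny depth | mean 8x per locus, gamma-Poisson dispersion 0.3 | matches the observed ~7x per progeny per polymorphic locus; the dispersion is a free parameter (no published value), chosen to give realistic depth dropout |
| parent depth | 2x progeny | parents loaded at twice the progeny amount |
| base error rate | 0.001 | typical high-quality short-read error |
| genome | 5 scaffolds x 300 kb, ~37% repeats, 5% gene models | desk-scale stand-in for an 804 Mb / 57% repeat assembly; see scaling below |
| recombination | 30 cM/Mb | scaling choice, see below |

Scaling.  The real assembly is ~800 Mb at ~0.9 cM/Mb.  A desk-scale
genome keeps sequence-level realism (real digest, real alignment) but at
0.9 cM/Mb a 300 kb scaffold would span 0.3 cM and carry essentially no
recombination, leaving nothing to map.  The generator therefore inflates
recombination density to 30 cM/Mb so that a scaffold spans ~9 cM and the
map has the same *structure* (several bins per scaffold, resolvable
order) as the full-size study.  Map positions and lengths are therefore
only comparable to truth within the simulation, never to the published
map; the recovery studies measure exactly that internal comparison.

Repeats.  Each repeat family has a consensus carrying one internal
NsiI-MseI fragment (families without cut sites are invisible to a ddRAD
assay and would only dilute the simulation); genomic copies diverge at
the family rate and keep intact cut sites with probability 0.15 per
copy (site decay by mutation), so most copies are alignment traps
rather than fragment sources.

Repeat presence/absence polymorphism.  With strict best-hit-unique
alignment, *identical* repeat copies only remove markers (ties are
discarded as ambiguous); they cannot mis-place one.  The mechanism that
creates genuinely mis-anchored markers — the phenomenon the
reference-strategy comparison is about — is a young transposon copy
present on one paternal haplotype but absent from the (maternal)
reference assembly: its internal ddRAD fragment yields reads with no
true reference locus, which align uniquely to the most similar fixed
copy of the family elsewhere in the genome.  The resulting cluster
looks like a clean paternal testcross marker physically located on the
wrong scaffold, and it disappears under repeat masking — reproducing
the headline contrast between the unmasked and masked references.  The
generator inserts such young copies (derived from a specific genomic
source element plus 1-2 private substitutions inside the tag) at 8
events per Mb on the paternal haplotype.  Interspecific crosses harbour
abundant transposon insertion polymorphism, so this rate is
conservative relative to real genomes; it is a study condition of the
simulation, stated here once.

What the generator does not model: PCR duplicates, adaptor chimeras,
quality decay along the read beyond a configurable mean, restriction
site methylation sensitivity, segmental duplications outside annotated
repeat families, and reference assembly errors.  Passing tests
therefore demonstrate correctness of the analysis chain under the
stated statistical structure, not robustness to every artefact of real
libraries.

## Read processing and alignment

Reads are demultiplexed by exact barcode prefix (the generator writes
exact, prefix-free barcodes; no 1-mismatch rescue), trimmed to 92
bases, and dropped when five or more bases fall below Q20.  The "five
nucleotides" exclusion rule is read as *at least* five sub-Q20 bases —
the conservative reading; the alternative (exactly five) would be
strictly weaker.

The aligner is seed-and-verify over the protocol's marker model: a tag
matches a locus with up to 2 mismatches and at most one indel event of
1-2 bp, scored as mismatches + 2 x indel bases.  Three non-overlapping
30-mer seeds (offsets 0/31/62) guarantee by pigeonhole that any
alignment within the 2-mismatch budget retains one intact seed;
verification is vectorized over all candidate positions.  A tag is
placed only when a single locus attains the best score; ties are
ambiguous and excluded downstream, which is exactly why repeat-masked
references *gain* usable markers in repeat-adjacent regions while
losing all repeat-internal loci.  Equivalence with an exhaustive
brute-force scan (hit set, best locus, tie handling) is asserted on a
20 kb two-scaffold genome with a duplicated block, over 1,000 planted
and random tags.

The original study's aligner settings are unpublished; the budget above
is taken from the marker definition (tags identical or with 1-2
mismatches / 1-2 bp indels), not from any aligner's defaults.

## Marker discovery and filters

Clusters are keyed by (scaffold, position, strand) of uniquely aligned
tags.  Discovery-panel filters and genotype rules, all exposed as
configuration with these defaults:

* cluster depth window 4-200x on the pooled parental panel (the
  discovery panel; progeny depth is handled per call);
* per-parent allele discovery: a parent's alleles are the tag variants
  carrying >= 25% of that parent's reads; the locus allele set is the
  union (more than two alleles = ploidy violation, locus discarded).
  Discovery is per parent rather than on the pooled panel because the
  homozygous parent otherwise dilutes the heterozygous parent's second
  allele to the threshold boundary;
* progeny calls need >= 3 reads; a locus must reach that in > 90% of
  progeny; for a testcross locus, carrying the heterozygous parent's
  alternate allele is diagnostic (an `np` call), which keeps
  undersampled heterozygotes from being silently miscalled;
* integrity: markers missing in > 10% of progeny are dropped;
* distortion: 1:1 markers dropped at class ratio > 3:1, intercross
  markers in dominant coding dropped at > 10:1 (both dominant codings
  checked).  A minimum of 10 informative calls is required for the
  ratio to be meaningful (the protocol is silent; ratios on fewer calls
  are noise).

The 25%-at->=3x heterozygote rule means a single second-allele read can
call a het at 3x; this known inflation is mitigated by the distortion
filter and documented rather than hidden.  Depth-3 genotyping errors
also inflate adjacent two-point estimates, which is why end-to-end
simulated map lengths run long; the marker-level recovery studies
(below) quantify map-length error without this read-level noise, and
the read-level comparison study uses concordance purity, which ordering
noise does not affect.

## Binning, mapping, anchoring

Recombination bins collapse markers with similarity score equal to the
progeny count — identical-or-missing in every progeny, under either
phase alignment — with a conflict veto against every current member.
Markers are processed in a canonical order (fewest missing calls, then
genomic coordinate), making the partition independent of input order;
the first member under that order is the representative.  Binning is
genome-wide by genotype identity; no physical-window constraint is
applied because none is defined in the emulated protocol.

Two-point estimation: same-parent testcross pairs use the closed form
r = R/N (phase minimizing r) with LOD = (N-R)log10 2(1-r) + R log10 2r;
any pair involving an intercross marker maximizes the joint progeny
class likelihood numerically over r in [0, 0.5] with both parental
phases enumerated.  Cross-parent testcross pairs are structurally
unlinked (different meioses) and fixed at r = 0.5, LOD 0.

Grouping thresholds are LOD >= 5.0 and r <= 0.25 (the thresholds that
produced the published map; the protocol's alternative maximum of 0.40
is available as configuration).  Groups are connected components;
singletons are reported unlinked.

Ordering is an original Stam-style incremental weighted-least-squares
placement: markers enter in decreasing information order (sum of pair
LODs), each insertion slot minimizes the LOD-weighted squared deviation
between fitted and observed pair distances (full WLS per slot for
groups up to 80 markers, a fixed-positions approximation above that),
followed by a window-3 ripple and, for small groups, a relocation /
segment-reversal polish, all accepting only improving moves.  Inside
the layout objective, pair distances are *Haldane* transforms of the
two-point estimates: under the no-interference crossover model Haldane
distances are additive in expectation, so long-range pairs agree with
sums of short ones and anchor the layout.  Using Kosambi distances in
the objective instead makes long-range pairs systematically shorter
than the corresponding chains of short pairs, which rewards folded
orders — measured on simulations, that variant folds a chromosome end
in roughly one dataset in twenty, and both obvious repairs (excluding
long-range pairs; inverse-variance weights) lose global anchoring and
do worse.  This choice affects only which order the layout prefers.
The reference software's internals are proprietary, so acceptance is
truth recovery on simulations — not output identity with that software.
Map positions are cumulative *Kosambi* distances over adjacent pairs
(the convention of the emulated protocol), with missing adjacent
estimates bridged by the shortest two-point path.

Anchoring assigns each scaffold to the modal linkage group of its
mapped bins (minority markers are logged, never split a scaffold —
scaffolds are treated as atomic), orders scaffolds by the mean cM of
their modal-group markers (mean rather than first marker position;
the choice is stated here because the emulated protocol does not say),
ties broken by descending length, and orients by the sign of the
Spearman correlation between physical and genetic positions (>= 2
distinct cM values required, else unoriented and placed forward).  AGP
v2.1 output uses 100 N gaps (no published value) with evidence tag
"map".  Orientation is meaningful only up to the arbitrary direction
of a linkage group; the recovery study scores it relative to the
estimated direction.

## Heterozygosity scan

Sites pass with depth in [10, 120] and minor-allele fraction >= 0.2
(the depth window is the protocol's; the caller's allele-fraction
threshold is unpublished, 0.2 is this package's documented stand-in).
Windows are 500 kb at 250 kb step, anchored at 0, terminal windows
truncated with their true length in the denominator.  The genome
average is the unweighted mean over scaffolds — the convention that
reproduces a printed per-scaffold column average — with a
length-weighted alternative available.  Note the emulated study reports
both a genome rate of 0.03% and per-scaffold densities averaging 0.33
per kb; these differ by ~10% (0.3 rounded), a discrepancy in the source
reporting that this package records without resolving.

## Study sizes used by the tests and drivers

Problem sizes are chosen so the whole suite runs on one CPU in minutes
while keeping every estimator in its operating regime: marker-level
recovery uses 20 datasets of 5 linkage groups x 40 markers at 2.5 cM
spacing, n = 51 (bins collapse to ~30 per group, the regime where
ordering is informative but not trivial); the read-level reference
comparison uses 10 seeds of the default 1.5 Mb genome; the aligner
oracle uses a 20 kb genome and 1,000 tags; the end-to-end smoke test
uses a 300 kb genome with 12 progeny.

## Known limitations

* Desk-scale genomes give sparse maps (tens of markers, not thousands);
  conclusions about *counts* are qualitative (orderings,
  accuracies), never absolute marker yields.
* End-to-end map lengths are inflated by depth-3 genotyping error;
  no error-tolerant binning or imputation is attempted (by design —
  the emulated protocol used hard calls).
* One chromosome spanning two linkage groups (the published map's 9
  groups vs 8 chromosomes) has no join rule in the source; none is
  implemented.
* The similarity-score bin criterion requires perfect compatibility; an
  error-tolerant variant exists as a config knob but is untested
  against the emulated results and off by default.
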