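# Methods

This note documents the models and conventions behind each stage of the
pipeline: what is computed, which parameters matter, what the synthetic
generators do and do not emulate, and where genuinely open design choices
were settled.

## Coordinates, formats, containers

All coordinates are 0-based, half-open. GFF3 is the one exception at the
file boundary (1-based, inclusive) and is converted on read/write.
Sequences are uppercase over `{A, C, G, T, N}`; anything else is rejected
with the record named. Motif and alignment searches consider both
strands; reported coordinates are always on the forward strand. FASTA is
read and written through Biopython, Newick through dendropy, tables
through pandas; the GFF3 shim keeps only the five fields the pipeline
uses (type, start, end, strand, label).

## Prophage detection

A prophage is called from a pair of same-strand occurrences of the
attachment motif whose separation lies inside a size window.

* `motif` — default `CAGATTTAGGTT`, the conserved 12-mer that marks
  attL/attR in this family; configurable.
* `max_mismatch` — Hamming tolerance per copy, default 1. Whether real
  att copies deviate from the consensus is not established, so the
  tolerance is a package choice; 2 is the allowed maximum (a 12-mer at 3
  mismatches is no longer informative against a ~5 Mb background).
* `size_window` — default (30 kb, 60 kb); the family's genomes span
  42–45 kb and the window is deliberately loose.

Overlap resolution keeps the shortest call per attL and then greedily
discards calls overlapping an accepted one; nested or chance repeats
otherwise create spurious giant calls. Opposite-strand pairings are
logged as warnings and never called: attachment sites are direct repeats
by integrase biology. The reported excision runs from attL start to attR
start — the circularised product carries exactly one att copy, mirroring
phages sequenced in circular form — and the prophage interval spans both
copies inclusive.

Circular rotation (`rotate_to_reference`) aligns an excision to a
reference origin by k-mer offset voting (k = 13): each shared k-mer votes
for a circular offset, on both strands, and the winning offset is
applied. At 5 % divergence about half of all k-mers survive, which is
ample; below ~5 shared k-mers the sequence is declared unrelated. The
exhaustive alternative (identity count at every rotation) is quadratic
and used only as a test oracle.

## GC regions

`gc_windows` uses 250-bp bins by default; the trailing partial bin is
kept with its own length weight, and N bases are excluded from numerator
and denominator (the genome mean therefore equals the weight-averaged bin
values exactly). Whether ambiguous bases should be excluded is not
settled usage; exclusion is this package's choice.

"Rest of the genome" is the complement of the early region (middle, late
and intergenic together). The early-vs-rest comparison is a paired
two-sided t-test with one (early, rest) value pair per genome — a panel
of 10 genomes gives 9 degrees of freedom, which is the only design
consistent with that df. The sign convention is rest − early, so the
GC-poor early region characteristic of recently transferred genes gives
a positive statistic.

## Intergenomic similarity

`pair_similarity` is VIRIDIC-style, not VIRIDIC-identical: the published
tool delegates to BLASTN, whose exact fragmenting and scoring this
package does not reproduce. Here genome A is cut into non-overlapping
1-kb fragments; each fragment's strand and diagonal against genome B are
chosen by 11-mer seed voting, and the candidate window (±150 bp of pad)
is aligned by edit distance (edlib) with the distance capped at 40 % of
the fragment length. Fragments whose best alignment exceeds the cap
count as unaligned. The directional similarity is

    100 × (identities / aligned columns) × (aligned columns / genome length)

and the reported value averages both directions, which also symmetrises
the matrix. The aligned-fraction weighting is what drives unrelated
sequences toward zero (their chance seed hits never pass the distance
cap), while identical genomes score exactly 100 with aligned fraction 1.
The 40 % cap means homology below ~60 % identity is treated as absence of
alignment; the measure is intended for the ≥ 70 % range where genus and
species thresholds live. Clustering is single-linkage (connected
components at a similarity threshold), matching how "clade above X %"
statements are made.

## Phenotype statistics

**RBG.** `RBG = 1 − ΔOD⁺/ΔOD⁻` over a fixed interval, per replicate
pair; `t0` defaults to the first reading (the assays start at
inoculation), `tx` is typically 10 h or 40 h. Readings are matched to
the nearest sample within half a sampling interval. The statistic is
invariant to blank subtraction and instrument gain. It is left
unclipped: when lysis drives the treated culture below its starting
density the value exceeds 1, which is information, not an error. A
non-positive control gain leaves the value undefined (flagged) rather
than dividing by it.

**Host range.** Deterministic grading of spot observations: no clearing
→ none; turbid clearing at high titre → weak; clear zone plus individual
plaques at dilution → strong; a strong spot that regrows and whose
colonies are PCR-positive for the prophage → lysogenization. Regrowth
without a PCR result keeps the grade strong with a `lysogeny-untested`
flag; a clear zone without plaques is graded weak, since lysis from
without cannot be excluded.

**One-step fits.** Work in log10 PFU. The rise is located at the maximum
slope between consecutive samples; baseline points are those at or
before the rise below 25 % of the log range, final-plateau points those
after it above 75 %. Both plateaus are **medians**, so a partially risen
sample that slips past the range threshold cannot drag the estimate; the
burst size is the plateau/baseline ratio and the latent period is where
the tangent through the max-slope segment meets the baseline. A series
whose plateau/baseline ratio is below 2 is flagged `no-rise` with the
latent period undefined. Validation is by recovery on simulated curves
(median latent error well under half the 30-min sampling step, median
relative burst error ~3 % at 5 % noise), not by parity with any
particular curve-fitting package.

**ANOVA.** Fixed-effects, type-I sums of squares in the order A, B,
A×B, via statsmodels OLS. Pairwise contrasts on the first factor's level
means use the pooled residual error and two-sided unadjusted p-values —
the convention under which such contrasts are usually reported — with an
optional Tukey HSD flag for adjusted values. A constant response returns
F = 0, p = 1 exactly rather than 0/0. Calibration: under a null 3 × 2 × 3
design the phage-term test rejects at the nominal 5 % (checked over 1000
simulations).

## Undated DTL reconciliation

The phage tree is mapped onto the host tree with four events:
cospeciation (cost 0 in the working setting), duplication (2), transfer
(1), loss (1 or 2, charged per host edge passed). The model is undated:
a transfer may land on any host node incomparable to the donor (neither
ancestor nor descendant), with no timing constraint — appropriate when
the input trees carry no node dates. Loss accounting is per-edge
passage, which is exactly what makes the loss-1 versus loss-2 settings
favour different explanations.

The dynamic program fills, for each phage node p and host node h:
`c(p,h)` (p's event at h), `in(p,h)` (p at or below h, one loss per edge
descended) and `out(p,h)` (best landing site incomparable to h).
Cospeciation requires the two phage children in distinct host child
subtrees; duplication keeps both within h's subtree; transfer keeps one
and moves the other to an incomparable node. The minimum over `c` at the
phage root is the answer. Solution counts are carried alongside
(sums over optimal choices, products over independent subproblems), so
MPR counting is exact; enumeration backtracks the tables in a fixed
order (cospeciation before duplication before transfer, host nodes in
postorder) and yields re-checkable certificates — every enumerated
reconciliation is re-evaluated bottom-up from its event list. The DP is
verified against a brute-force enumeration of all complete event
histories on every small tree shape.

MPR clustering uses the symmetric difference of event sets as the
distance — no standard metric exists for reconciliations, so this choice
is declared rather than asserted as parity with any tool — with
deterministic k-medoids (farthest-first seeding, alternating
refinement); the representative of a cluster is its medoid. The cost
space scan fixes cospeciation and duplication costs, sweeps a (transfer,
loss) grid, records the minimum cost and the set of optimal event-count
signatures per cell, and merges 4-connected cells with identical
signature sets into regions. The significance null permutes the
phage-to-host tip associations uniformly (`p = (1 + #{null ≤ observed}) /
(n_perm + 1)`); a uniform random-topology null on the same tips is
provided as an alternative, since "random trees" can mean either.

## Synthetic data

The generators produce data with the statistical structure the analyses
assume; they are the package's test bed, not models of any particular
laboratory system.

* **Phage genomes** — length uniform on 42–45 kb; early/middle/late
  regions as fixed fractions (early = first 19 %); per-region GC placed
  by exact composition (the target count of G+C bases, shuffled), so
  region means hit their targets to rounding. Defaults: early 0.5432,
  rest 0.5995. Occurrences of the att motif within one mismatch on
  either strand are removed by reshuffling the offending window (which
  preserves GC exactly). No gene content, codon structure or
  substitution process is simulated.
* **Host genomes** — 100 kb segments at GC 0.607 carrying the att motif
  exactly once, inside an 85-bp tRNA-Leu feature; all other near-matches
  of the motif are screened out, so the synthetic host has a single
  unambiguous attachment site. A real 7-Mb chromosome would carry a few
  chance near-matches; the detector's specificity against such
  background is a property of the window pairing, not tested by these
  genomes.
* **Lysogens** — host att site becomes attL, phage inserted, second
  motif copy appended as attR; the interrupted tRNA is relabelled.
  Optional single-base mismatches in either att copy model degenerate
  sites.
* **Infection OD curves** — three compartments (susceptible cells S,
  lysogens L, free phage P), RK4 at 0.5-min steps, logistic growth
  (r = 0.3 /h, K = 1.0 OD), mass-action adsorption (5 per OD·h), burst
  yield 50 (scaled units), lysogenisation probability q (0.01 default; 0
  disables lysogeny), free-phage decay 0.05 /h; sampled every 20 min over
  72 h with multiplicative lognormal noise (sd 0.02). With q > 0 the
  phage+ culture crashes and recovers as lysogens take over; with q = 0
  it crashes and stays down. The model has no latency compartment, so
  the `latent_min` parameter is carried for reference but unused here;
  the kinetic constants are order-of-magnitude choices for slow-growing
  rhizobia, exposed in `InfectionParams` rather than asserted.
* **One-step curves** — PFU flat at `i0` until the latent period, then a
  cubic smoothstep in log10 over a 30-min rise to `i0 × burst`. The
  smoothstep (rather than a logistic) reaches the plateau exactly, so
  the noise-free plateau/baseline ratio equals the burst size exactly;
  the tangent construction recovers the latent period to within one
  sampling step either way. Sampling every 30 min over 8 h; lognormal
  noise.
* **Cophylogeny scenarios** — host tree from a timed pure-birth process
  (rate 1 per lineage); a single phage lineage enters at the root,
  cospeciates at every host split, and on each host edge may (with
  per-edge probabilities, at most one optional event per traversal) be
  lost, duplicate, or transfer at a uniform time to a host edge alive at
  that moment, excluding the donor — the undated-DTL notion of an
  eligible recipient. The recorded history is the full one, including
  events on lineages that later die out; extinct lineages are pruned
  from the returned tree. This makes the parsimony bound exact: the
  minimum reconciliation cost of the pruned pair never exceeds the full
  history's cost. If every lineage dies the simulator raises an error
  suggesting a lower loss rate.

Because the generators hit their GC targets by construction, screen
their own motif background, and produce noise from known distributions,
passing tests demonstrate correctness of the algorithms under the stated
assumptions — not robustness to mosaicism, repeats, assembly artefacts,
plate-reader drift, or model misspecification in real data.

## Problem sizes

The test suite and the acceptance script run at deliberate scales: all
tree-pair shapes up to 5 tips per side against the brute-force oracle
(192 pair/map combinations, three cost settings), 100 simulated lysogens
and 100 phage-free genomes for detection, 10-genome GC panels, 1000 null
ANOVA simulations, 999-replicate permutation tests on 9-host scenarios,
and megabase genomes only for the motif-scan oracle. These sizes give
stable statistics while keeping the whole suite in the minutes range on
one CPU.
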