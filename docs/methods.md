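# Methods

## Splicing index and exon filters

The splicing index SI(e, s) is the ratio of exon rpkm to host-gene rpkm
in one sample.  Because the per-sample library-size factor appears in
both numerator and denominator, SI reduces to
(c_e/l_e)/(c_g/l_g) and is invariant to depth; the library size used for
standalone rpkm values (the MA-plot x-axis) is the column sum of the
gene count table.  SI is computed per replicate and then averaged per
condition rather than pooling counts first: the per-replicate values are
needed anyway for the variability screen, and one code path keeps the
two uses consistent.  SI is undefined (NA) in samples where the gene
rpkm is zero.

Fold change is log2(mean SI control + ε) − log2(mean SI knockdown + ε)
with ε = 10⁻³ by default (configurable).  The minimum-reads filter
guarantees one condition is expressed, but the other may be all zeros;
the pseudocount keeps the fold change finite while barely perturbing
values in the typical SI range of 0.1–1.

Filters, in order:

* **multi-exon**: genes contributing a single exon are removed (an SI of
  a lone exon carries no usage information).
* **minimum reads**: an exon is kept only if, in at least one condition,
  every replicate has strictly more than 5 reads.  The inequality is
  strict: counts of (5, 9, 9) fail.
* **low variability**: Fano factor (sample variance with n−1
  denominator, divided by the mean) of the replicate SI values within
  the designated condition — the knockdown triplicates by default —
  must be below 5×10⁻⁴.  With three replicates the n−1 variance is the
  unbiased choice.  A zero mean leaves the Fano factor undefined and
  the exon is dropped.

## Moderated statistic and randomization FDR

The per-exon statistic is d = (mean₁ − mean₂)/(s + s0) with the pooled
standard error s and background variance constant s0 = 0.1.  s0 bounds
the denominator away from zero so exons with tiny replicate variance
cannot reach arbitrarily large statistics; as s0 → ∞ every d → 0 and
nothing is called.

The null ensemble is either (a) label permutation — all C(n, n₁)
condition assignments enumerated exhaustively whenever there are at most
10 000 (a 3-vs-3 design gives exactly 20, identity included), otherwise
a seeded Monte-Carlo sample — or (b) Gaussian attribution: each exon's
values are redrawn from one Gaussian with that exon's pooled mean and
pooled (n−1) SD, destroying any condition effect while keeping the
per-exon location/scale structure.

q-values follow the moderated-statistic convention: for exon *i*, the
numerator is the median across randomizations of the per-randomization
count of null |d*| ≥ |d_i| and the denominator is the observed count of
|d| ≥ |d_i| (at least 1, the exon itself).  The ratio is clipped to
[0, 1] and monotonized step-up style: each exon receives the smallest
estimate attained at any threshold it passes, so q never increases with
|d|.  The null proportion π₀ is fixed at 1, which is conservative.
Exceedance counting is two-sided on |d|; direction calls come from the
sign of the SI log2FC.

## Preranked enrichment

Only preranked mode is implemented: the rankings of interest (SI log2FC,
PPS) arrive as scored lists, so phenotype permutation is not possible.
The running sum increments by |score|^p / Σ_hits|score|^p at members and
decrements by 1/(N − N_hits) at non-members; ES is the signed maximum
deviation, attained at the first peak when tied.  The default weight is
p = 1 (configurable to 0); if every member score is zero at p = 1, the
weights fall back to uniform rather than dividing by zero.  Ties in the
ranking metric keep stable input order for determinism.

The null is random same-size member draws (the preranked convention).
NES divides ES by the mean magnitude of same-sign null ES; null scores
are normalised identically and pooled across sets for the FDR, computed
one-sided within the observed sign.  Reported FDR is floored at
1/n_perm, and `format_fdr` renders floored values as a bound
("<0.001") rather than a false zero.  The randomization control
re-runs the procedure after shuffling scores across identities; a real
enrichment must vanish under it.

## Phosphoprotein score

PPS is the plain per-protein sum of site log2 fold changes — additive,
order-independent, and sensitive to both the magnitude and the number of
responsive sites.  Duplicate (protein, site) rows are rejected rather
than silently summed, because the same residue observed in several
peptides must be aggregated upstream or it double-counts; rows with a
missing fold change are dropped with a logged count, matching
quantification dropout.

## FRET efficiency mapping

F% = 100·(IF − kD·ID − kA·IA)/IA.  kD (donor bleed-through into the
transfer channel) is the median of IF/ID over a donor-only control; kA
(acceptor cross-excitation) the median of IF/IA over an acceptor-only
control.  The median is robust to hot pixels and near-zero denominators.
Because the formula divides by IA, pixels where IA is at or below an
intensity floor are masked; the default floor is 5% of the IA channel
maximum (the maximum is used as the dynamic-range scale because the
minimum-to-maximum span degenerates on flat synthetic images).  ROI
masks are inputs — nuclei are hand-selected in this kind of experiment —
and per-ROI output is the arithmetic mean of valid pixels with the pixel
count.

## Synthetic data: what it emulates and what it does not

The differential generator draws per-gene totals from a negative
binomial (Gamma–Poisson; Var = μ + φμ²) and each exon's count as a
binomial thinning of its gene's count with success probability
ψ·l_exon/l_gene.  Consequences: exon counts can never exceed gene
counts, and SI estimates ψ directly, so the truth table's ψ values are
the analytic ground truth for every downstream check.  Planted exons
shift ψ by ±delta_psi between conditions ("up" = more included in
control).

Defaults (chosen once as a realistic deep bulk RNA-seq triplicate
design): 3 replicates per condition; mean gene expression 5000 reads;
NB dispersion 0.05 (typical for biological replicates of a cell-culture
knockdown); gene length fixed at 2000 nt and exon lengths uniform on
[50, 500] nt so rpkm length normalisation is exercised without
dominating variance; baseline ψ uniform on (0.25, 0.6) so that
ψ + delta_psi stays below 1 at the default shift of 0.3; about 2% of
genes receive a single exon (Poisson draw), exercising the structural
filter.  The real data's dispersion is not known; these values are for
testability, not parameter inference.

Not emulated: read-level artefacts (GC bias, positional coverage,
mapping ambiguity), correlated exon usage within a gene, batch effects,
or motif-driven targeting.  Passing tests therefore demonstrate the
statistics are correct and calibrated under the assumed count model,
not that the model captures every property of real libraries.

The null generator ("Gaussian attribution") gives every exon one shared
mean (uniform on [0.1, 1.0]) and i.i.d. Gaussian replicate noise
(σ = 0.05 by default) — no condition effect anywhere, for FDR
calibration.  The phospho generator distributes a requested total of
sites over proteins (each keeping at least one) with background site
fold changes centred at zero and one planted protein whose sites share a
common mean.  The FRET generator synthesises the transfer channel by
inverting the efficiency formula, plus optional Gaussian read noise, and
emits matched single-fluorophore control stacks.

## Evaluation protocol choices

Recovery of planted exons (sensitivity, sign agreement, empirical FDR)
is measured over the exons that enter the test, i.e. those passing the
structural and minimum-reads filters.  The Fano screen is deliberately
not part of that denominator: it is a variance pre-selection whose pass
rate is a property of sequencing depth — under realistic coverage it
excludes a large fraction of exons regardless of whether an inclusion
change was planted — so including it would measure the screen's
selectivity, not the detector's power.  The screen itself is
default-on in the pipeline and tested separately.

Problem sizes in the test suite (8457-exon null tables over 20 seeds,
~2500-exon planted datasets, 5000-item rankings with 500–1000
permutation draws) were chosen to give stable pass/fail behaviour at
interactive runtimes.

## Known limitations

* The 3-vs-3 permutation null has only 20 assignments, so per-exon
  q-value resolution is coarse; significance at small q relies on the
  across-exon exceedance pooling, as in the moderated-statistic
  tradition.
* π₀ = 1 makes q conservative when many exons are truly changed.
* The enrichment FDR for a single set reduces to a one-sided null tail
  probability; with few sets the pooled-null convention is noisy below
  ~1/n_perm.
* PPS weights every site equally; a protein with many weakly responsive
  sites can outrank one with a single strong site.
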