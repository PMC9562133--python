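# Methods

This note records the models, parameter choices and numerical conventions
behind `tandemscape`, and what the synthetic experiments do and do not
demonstrate.

## Tandem detection

A gene's *rank* is its 0-based index in start-coordinate order within its
chromosome (ties broken by end coordinate, then gene id, so ranks are
deterministic). Homology comes from a 12-column outfmt-6 table and is
filtered in three steps: self-hits dropped; E-value strictly below
`evalue_max` (default 1e-10, matching an "E < 1e-10" search setting); per
query only the `top_n` (default 10) best distinct subjects kept, ranked by
bitscore with ties broken by E-value then subject id — a deterministic
reproduction of a `-max_target_seqs`-style cap. Homology is then treated
as undirected: a pair survives if either direction survives (tandem
duplication is a symmetric relation).

A tandem pair is a surviving homolog pair with rank distance ≤ `max_gap`
on one chromosome. `max_gap` defaults to 1 (strictly consecutive genes),
the conservative reading of "adjacent duplicates"; field pipelines differ
here, so the parameter is exposed everywhere. Clusters are connected
components of the tandem-pair graph; by construction no cluster spans
chromosomes and no gene belongs to two clusters. Report percentages
(per-chromosome distribution, TDG fraction of the gene set) are rounded
half-up to two decimals.

## Ka/Ks (NG86) and dating

Protein pairs are aligned globally (Needleman–Wunsch, BLOSUM62, affine
gaps: open −10, extend −0.5) via Biopython's `PairwiseAligner`; among
co-optimal alignments the aligner's first enumeration is used, which is
deterministic. The alignment guides back-translation: each amino-acid
column becomes its source codon, protein gaps become `---` columns, and
columns containing a gap, stop or ambiguous base are excluded.

NG86 counting: the synonymous site count of a codon is, per position, the
number of synonymous single-nucleotide changes divided by 3 (changes
creating a stop count as nonsynonymous); S is averaged over the two
sequences, and N = 3·(included codons) − S. Differences between a codon
pair with k differing positions are averaged over all k! substitution
orders, each step classified by the universal genetic code (injectable for
other codes). A pathway passing through a stop codon is dropped; if every
pathway drops, the codon pair is excluded from both sites and differences.
Proportions pS = Sd/S and pN = Nd/N are corrected with Jukes–Cantor,
d = −(3/4)·ln(1 − (4/3)p), undefined at p ≥ 0.75: such estimates are
flagged saturated/undefined rather than clamped. Classic equal-weight
pathway averaging is used (no transition/transversion weighting) because
it is exactly checkable against a brute-force pathway enumerator, which
the test suite does to 1e-9.

Ka/Ks < 1 (beyond 1e-9 tolerance) is labelled negative selection, ≈ 1
neutral, > 1 positive; the ratio is undefined when Ks = 0 or saturated.
Report tables round the ratio half-up to two decimals; full precision is
retained internally.

Divergence time is T = Ks/2λ in years, reported in Ma to one decimal.
λ defaults to 1.5×10⁻⁸ synonymous substitutions per site per year, the
usual grass clock — the value that maps Ks 0.6–0.7 to 20.0–23.3 Ma and
Ks 2.5 to 83.3 Ma — and is configurable.

Within a cluster, Ka/Ks is computed for consecutive-rank member pairs (a
size-k cluster yields k−1 pairs). Computing all within-cluster pairs would
overweight large clusters with highly correlated comparisons; the choice
is recorded in `kaks_meta.json` alongside every run.

## Ks landscape

Ks values that are undefined, non-finite or above `ks_cap` (default 3.5,
just beyond where NG86 saturates and above the oldest expected peak) are
dropped before histogramming into fixed bins [k·w, (k+1)·w), w = 0.1 —
chosen so a peak is naturally reported as an interval like [0.6, 0.7).
The primary peak is the modal bin (first on ties); secondary peaks are
local maxima with ≥ 25% of the modal count and ≥ 3 bins of separation,
accepted in descending count order. Peak reporting needs ≥ 20 values;
below that the histogram is still returned. Each peak is dated both as an
interval and at its midpoint via T = Ks/2λ, since a "peak Ks" is
ambiguous between the two conventions.

For per-class comparison a pair takes an expression class only when both
members share it; discordant pairs are "mixed" — kept in the whole-set
distribution, excluded from class plots. Classes + mixed + unclassified
therefore partition the whole set exactly (tested as a conservation
invariant).

## Enrichment

Over-representation uses the hypergeometric upper tail P[X ≥ k] for a
term with n background genes, k of m study genes, background N (SciPy's
`hypergeom`), corrected with Benjamini–Hochberg across tested terms. Only
terms with k ≥ 1 are tested, which fixes the BH denominator to the number
of tested terms; the background is the annotated gene set (standard ORA
practice), both documented in output. Significance is q ≤ 0.05; the
cutoff is configurable and recorded. The rich factor is k/n. Set
comparison assigns every term of the union to exactly one region keyed by
the subset of species sets containing it.

## Salt-response classification

FPKM[g,s] = counts · 10⁹ / (library_size · length). `simple_de` is a
deliberately simple stand-in DE test so the classifier can run from raw
counts: CPM normalisation, log2 fold change of mean CPM with pseudo-count
0.5, Welch t-test on log2 CPM across replicates, BH per contrast. It has
far less power than a negative-binomial GLM at n = 3 replicates; real
analyses should supply a DESeq2-style DE table directly, which the
classifier consumes unchanged.

Up-regulation is one-sided: FDR ≤ 0.05 **and** log2FC ≥ +1 (the DEG
threshold uses |log2FC| in general, but only up events feed this
classifier). Events are counted per (gene, tissue) across timepoints.
Classification: tissue-specific iff ≥ `spec_min` (4) events in one tissue
and ≤ `other_max` (1) in the other; otherwise co-expressed iff the total
across both tissues ≥ `co_min` (7); otherwise unclassified. With five
timepoints per tissue, "at least seven times in both tissues" cannot mean
seven per tissue, so the total reading is implemented; specificity is
checked before co-expression, which cannot co-fire at the defaults but
guards larger designs. All thresholds are configurable; the tissue list
is parameterised (default leaf/root) rather than hard-coded.

## Synthetic data

The generator's defaults emulate the study design it stands in for: two
tissues (leaf, root), 400 mM NaCl treatment vs water control at five
timepoints (8 h–5 d), three biological replicates, tandem arrays of 2–9
genes, and a 48/116/138 leaf/root/co-expressed response split (total 302).

Genome: gene lengths are log-normal in codons (median 300, σ = 0.3,
minimum 100 — stable NG86 estimation needs ≥ ~100 codons), laid out with
a fixed 500 bp intergenic gap; these layout constants are arbitrary but
documented and seed-reproducible. Cluster members descend from one random
ancestor (star topology), each branch carrying half the target
divergence, so every member pair meets the target Ks in expectation.
Background genes are independent random CDS and share no homology.

The codon substitution simulator is independent of the NG86 estimator it
tests: per branch it draws Poisson numbers of synonymous and
nonsynonymous events (rate × expected NG86 site count of the ancestor),
then places each event by uniform (codon, position, base) proposals,
accepting a proposal when it realises the requested synonymy without
creating a stop. Events therefore land uniformly over NG86 opportunities
and multiple hits arise naturally, which the Jukes–Cantor correction then
removes. Empirically the estimator recovers the target within ~4% at
Ks ≤ 1; beyond Ks ≈ 2 an increasing fraction of pairs saturates and the
conditional mean drifts upward, so old-burst recoveries are only checked
at wide tolerance.

The homology emulator emits every within-cluster pair in both directions
at E ≪ 1e-10 plus self-hits; spurious noise pairs are constrained to rank
gaps > 5 or different chromosomes, so noise can create background edges
but never a false tandem pair nor a bridge between planted arrays. The
expression generator's DE tables are the primary product (planted events:
log2FC ~ N(2, 0.15), FDR ≤ 1e-3; null: log2FC ~ N(0, 0.2), FDR ≥ 0.2),
giving a high-signal regime in which classifier recovery is exact; the
accompanying negative-binomial counts (dispersion 0.05) exercise FPKM and
`simple_de`, where recovery is *not* exact — that contrast is the point
of shipping both.

What passing the synthetic suite shows: the detection, counting,
correction, enrichment and classification machinery is correct against
independent oracles and planted truth. What it does not show: robustness
to real-data pathologies — fragmented annotations, alignment errors,
paralog conflation in BLAST, dispersion misspecification, unbalanced
designs — which the simulator deliberately does not model.

## Problem sizes and determinism

The default synthetic study (2 × 500 genes, 60 arrays, ~260 Ka/Ks pairs)
runs in seconds; tests use smaller layouts and the statistical checks use
200 replicate pairs per condition, sized for tight sampling error on a
mean while staying fast. All randomness flows from a single seed through
named per-stage substreams (`numpy.random.default_rng([seed, stage])`),
and a repeated run with the same seed produces byte-identical text
outputs (tested). Degenerate inputs have defined behaviour: empty TDG set
→ empty table; empty codon alignment → error; saturated estimates →
flagged undefined, never silently clamped; Ks = 0 → undefined ratio.
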