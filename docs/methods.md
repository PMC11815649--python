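# Methods

## Tag chemistry and the channel model

The TMTpro label (+304.2071 Da as a peptide modification, composition
C15H25N3O3 with nine heavy substitutions) is modeled as three regions: the
reporter (C8N1, observed as the C8H16N+ cation series at 126.1277+),
the carbonyl carbon that departs with the reporter during fragmentation,
and the complement region (C6N2O2 plus the carbonyl oxygen) that stays on
the peptide. The eighteen commercial tags place 7x13C+2x15N or
8x13C+1x15N among these regions; the per-tag placement encoded in
`chem._TAG_LAYOUT` reproduces the published reporter-ion exact masses and
is the unique assignment, under the region capacity constraints, for which
the eighteen complement masses fall on nine nominal-mass groups. Members
of a group differ by at most one 13C-for-15N swap (6.32 mDa), far below
the default `resolvable_dm = 0.02 Da`, which in turn is far below the
~1 Da channel spacing — so the channel model is insensitive to the exact
threshold over two orders of magnitude. Channels are ordered by
complement mass and named c1..c9; which physical sample sits in which
channel is a labeling-scheme convention outside the model.

Isotope envelopes are aggregated (unit-mass binned): per-element
multinomial offset distributions are convolved by truncated polynomial
exponentiation. Fine structure within a bin is below the modeled
resolutions and is handled only through `resolvable_dm`. Heavy-substituted
atoms are treated as isotopically pure.

## Cluster prediction and extraction

The default loss model is a singly charged reporter fragment plus neutral
CO, giving complement charge z_c = z-1; a neutral-loss variant (z_c = z)
is available, and the departing mass can be overridden. The cluster
template uses a uniform grid of `1.00335 / z_c` from the channel-0
position; the ~6 mDa deviations of individual channels from that grid are
unresolvable at 45-120k and are absorbed by the 10 ppm matching tolerance.
Extraction takes the most intense centroid within ±10 ppm of each expected
position; when two positions claim one centroid the closer position wins.
Unmatched positions contribute zero intensity and the noise floor.

## Deconvolution

Design-matrix column c is the convolution of channel c's complement-region
impurity vector (mean over its member tags, which are indistinguishable by
construction) with the peptide envelope, shifted to the channel offset.
The envelope is truncated at the first length retaining 99.9% of its mass
and renormalized, so columns conserve signal; mass falling off the
observed rows (sub-grid -1/-2 impurities of the lowest channels, trailing
isotopes beyond the last row) is simply lost and keeps column sums <= 1.
Two trailing isotope rows beyond the last channel keep the system
overdetermined (11 rows x 9 channels by default).

The solve uses LAPACK's `gelsy` (complete orthogonal / QR factorization).
Negative components are clipped to zero after the solve — abundances are
physical, and on noiseless data the solution is exact so clipping is a
no-op; a full non-negative least-squares fit is available via
`nonnegative=True` because whether the published analysis constrained the
sign is not stated. Rank deficiency is rejected with the collinear channel
pair named. The quantification gate uses the total matched-peak
signal-to-noise (sum over all cluster peaks, not per channel): >= 90 for a
9-plex, else 10 per labeled channel.

The measured impurity magnitudes of the commercial tags are not public in
this codebase's sources, so the bundled table
(`data/impurities_default.tsv`) is a deterministic synthetic stand-in with
realistic magnitudes: -1 impurities proportional to the region's heavy-atom
count (0-2.8%), +1 impurities 1.0-1.6%, smaller +/-2 terms. Simulator and
deconvolution read the same table (configurable via file), so correctness
of the inversion is testable independently of the true values.

## The interference simulator

The simulator emulates the two-proteome design: a "yeast" proteome at
design ratios 0:1:5:10:1:10:5:1:0 across c1..c9 and a "human" proteome at
1:1, mixed 1:10. Peptides are random tryptic-like sequences (length 8-20,
K/R terminus, uniform residue frequencies — composition realism only
matters through the isotope envelope), charge 2+ (60%) or 3+ (40%), drawn
until precursor-eligible. Expected cluster intensities are the design
matrix applied to the channel truth, scaled to `ion_scale` (default 5000)
expected ions per cluster; observed counts are Poisson draws and the
reported per-peak noise is sqrt(counts + floor^2) with floor 5 ions.
Reporter-region peaks (with reporter impurities, deliberately uncorrected)
are emitted for every coisolated species.

With probability `coisolation_prob` (default 0.5) an interferent — a
second random peptide at 1:1 channel ratios whose precursor sits within
the 0.5 Th isolation window — contributes `interferent_fraction` (default
0.5) of the target's ions. Its complement cluster lands at its own
peptide-specific positions; its reporter ions land exactly on the shared
reporter positions. Centroids closer than the FT peak width
`dm = m^1.5 / (R200 * sqrt(200))` coalesce intensity-weighted; the default
resolution setting is 60k (the fractionated-acquisition setting), and the
width constant is a configuration knob.

Because coisolated precursors have nearly equal m/z, an interferent whose
mass differs from the target's by close to an integer number of daltons
interleaves its whole cluster with the target's within the peak width.
This is a genuine resolution effect — it compresses or inflates individual
PSM ratios and is why the per-PSM complement ratio distribution is
heavy-tailed under interference. Run-level complement accuracy is
therefore summarized by the **median** per-PSM ratio, the statistic used
for instrument ratio benchmarking in this field; reporter compression is
monotone and shows up in median and pooled means alike.

What the simulator does *not* model: chromatographic elution and dynamic
exclusion, AGC/injection-time control (abstracted into `ion_scale`),
fragment backbone ions, charge-state errors, and real impurity values.
Passing tests demonstrate the correctness of the inversion and the
interference asymmetry under these idealized acquisition statistics, not
instrument-level sensitivity figures.

## Time-course analysis

Peptides shared between proteins follow the razor rule (assigned to the
candidate with the most unique peptides, lexicographic tie-break). Stage
normalization scales each column so the summed anchor-peptide signal
(median optional) is level, preserving the pre-normalization mean; the
operation is idempotent and removes any per-stage acquisition drift up to
one global factor. "Median-corrected" roll-up is interpreted as: scale
each peptide profile to its own mean, take the per-stage median across the
protein's peptides, and rescale to the peptides' summed signal; a
single-peptide protein keeps its profile exactly.

Clustering is hierarchical k-means: rows are normalized to fractional
profiles (so clusters reflect trajectory shape, not abundance), a Ward
cut at k initializes the centroids, and Lloyd iterations run to
convergence — deterministic for a fixed input, and invariant to row order
up to label permutation. A two-pass schedule (cluster at k1, isolate one
cluster, recluster the remainder at k2) reproduces the
separate-the-maternal-cluster workflow. Fold-change summaries report
log2(first/last) per protein (positive = decreasing), with zeros floored
at half the smallest positive matrix value and flagged.

The time-course generator draws proteins from four archetypes (constant,
2^±1.5 ramps, a Gaussian peak), flags a fraction of the constant class as
anchors, and applies multiplicative lognormal noise (default sigma 0.1)
per peptide and stage.

## Problem sizes and numerical tolerances

Acceptance-level checks use 100 noiseless peptides for exact ratio
recovery (tolerance 1e-6 relative; the noiseless pipeline is consistent by
construction, so recovery is limited only by floating point), 500 PSMs at
5000 ions/cluster for the stochastic and interference properties (median
within 5-10%), 1000 random 12x9 systems against a normal-equations oracle
(1e-8 relative), and 200 proteins for clustering recovery (ARI >= 0.95).
These sizes give comfortable Monte-Carlo margins for every asserted
tolerance while keeping the full suite under a minute.
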