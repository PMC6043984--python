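# Methods

This note records the models, conventions and numerical choices behind
`telopirna`, and what the synthetic-data generators do and do not emulate.

## Small-RNA preprocessing

Reads are clipped by scanning for the leftmost offset at which a prefix of
the 3′ adapter aligns with at least `min_overlap` bases (default 6) and a
mismatch fraction ≤ `max_mismatch_rate` (default 0.1); `N` never matches
anything, including another `N`. Reads in which no adapter is found are
dropped by default (the modelled libraries were fully adapter-ligated); a
keep-unclipped policy is available for pre-trimmed inputs. The length
filter retains reads ≥ 19 nt ("> 18 nt"); no upper bound is applied at
this stage because the piRNA/siRNA partition happens later, on mapped
reads. Identical sequences are collapsed into one record with a
multiplicity, and the sum of multiplicities before mapping is kept as the
reads-per-million denominator — normalization is to *sequenced* reads, not
mapped reads, so RPM values from different references share a scale and a
fully mapped library totals exactly 1,000,000 RPM.

The adapter sequence and clipping parameters are configuration, not
reconstruction: small-RNA protocols vary, and the defaults (min_overlap 6,
10% mismatch) are ordinary small-RNA practice.

## Mapping model

Alignment is ungapped with a mismatch budget k ∈ {0..3}, reporting every
placement on both strands (minus-strand placements compare the reverse
complement of the read). This is the appropriate model for 19–29-nt reads
and matches the semantics of classic short-read aligners in ungapped mode.
The implementation vectorizes the per-offset Hamming comparison with numpy
sliding windows; the exhaustive scan is the normative definition, and the
test suite holds the implementation to set-equality with an independently
coded brute-force oracle at every offset, strand and budget.

Coordinates are 0-based half-open internally. A hit's `five_prime_pos` is
the reference coordinate of the read's biological 5′ end: the interval
start on the plus strand, the interval end − 1 on the minus strand. All
positional statistics (coverage windows, ping-pong overlaps) are defined
on 5′ ends, because piRNA biogenesis signatures live at the 5′ end.

Multi-mappers: by default a read distributes its multiplicity evenly over
its placements (fractional weights, totals conserved); a `count_all`
option gives the read full weight on every placement, the convention used
when plotting per-element profiles of multi-copy families. The choice is
recorded in the output metadata. Recommended budgets: k = 0 for transgene
analyses (unique sequence, exact evidence), up to k = 3 for canonical
retrotransposon consensus sequences, which individual genomic copies match
only approximately.

## Cluster statistics

*Coverage* counts hit weights by 5′ end in fixed windows (default 30 bp;
the last window may be short), RPM-normalized; a full-span pileup mode is
available but windowed 5′ counting is the default because the profiles
represent read counts, not base coverage.

*Length classes*: piRNA = 24–29 nt, siRNA = 21 nt, everything else
"other". The 1U bias is the multiplicity-weighted fraction of 24–29-nt
hits on one strand whose first sequenced base is T (U in RNA). Zero
eligible reads yields NA, never 0 — absence of data is not absence of
bias.

*Ping-pong*: reads are collapsed to weighted 5′-position classes per
strand; for overlap o ∈ {1..30}, pair_count(o) = Σ_s w⁺(s) · w⁻(s + o − 1),
so a canonical pair scores o = 10. This class-product counting is exact
and avoids the quadratic blowup of all-vs-all read pairing. The Z-score
standardizes pair counts against the mean and sample standard deviation
(ddof = 1) of the background bins, which exclude the signal bin o = 10 —
the conservative convention, since including the signal deflates it; both
the background definition and the exclusion are configurable and echoed in
the output. Degenerate inputs (a single represented strand, or zero
background sd) return all-zero Z-scores with an explicit flag.

## Read simulator

`simulate_library` draws a mixture of piRNAs (fraction 0.70 by default),
21-nt siRNAs (0.15) and background degradation fragments of 19–29 nt
(0.15) from a reference sequence. piRNA lengths follow a categorical
distribution over 24–29 nt peaked at 25–26 nt, as in fly ovarian
libraries; the primary-piRNA 5′ base is U with probability `u1_prob`
(default 0.75). Defaults model a productive dual-strand cluster
(`strand_ratio` 0.5) with a moderate ping-pong loop (`pingpong_fraction`
0.30) and error-free bases unless asked otherwise.

Two design points matter for interpretation:

- The 1U bias is planted by sampling 5′ positions whose reference base
  matches the drawn first-base class, so error-free reads remain exact
  substrings and map at k = 0. Measured 1U on the piRNA class is therefore
  *diluted* relative to `u1_prob` by ping-pong partner reads and by
  background fragments of piRNA length — exactly as responder piRNAs and
  degradation products dilute 1U in real libraries.
- `pingpong_fraction` p is the fraction of piRNA *reads* that belong to a
  planted pair (round(p·n) reads forming whole pairs); the partner's 5′
  end sits exactly 9 nt downstream on the opposite strand (overlap 10).

A single seeded generator drives all sampling in a fixed order, so a fixed
seed reproduces the FASTQ byte for byte. The simulator does not model
ligation bias, PCR duplication or phased (trailing) piRNA biogenesis;
passing recovery tests therefore demonstrates correctness of the
estimators under the stated mixture model, not robustness to
protocol-specific artifacts of real libraries.

## 3D geometry

Stacks are (z, y, x) arrays with physical voxel sizes (dz, dy, dx); the
default dz of 1.05 µm reflects the confocal slice step of the stacks this
pipeline models, with 0.2 µm in-plane. Nucleus segmentation is a
threshold (fixed or Otsu) with largest-26-connected-component selection
and hole filling — a stand-in for interactive manual segmentation so runs
are unattended; a supplied mask is accepted unchanged. Spots are
26-connected components above threshold with a minimum voxel count
(blob-like objects); the nuclear surface uses 6-connectivity (mask voxels
with a 6-neighbor outside), which gives a watertight surface.

The "growing-sphere" distance — grow a sphere from the cluster center
until it touches the nuclear surface and record the radius — is computed
as the minimum Euclidean distance from the point to any surface-voxel
center in physical coordinates; the two definitions are mathematically
identical, and the brute-force minimum is the normative definition any
accelerated implementation must match exactly. Points outside the mask
return a negative distance as an explicit flag. Centers of mass are
intensity-weighted by default (an unweighted option exists), with voxel
centers at (index + 0.5) · spacing. Cluster diameter is twice the largest
XY distance from the center to a member voxel in the z-slice containing
the center of mass, floored at one XY voxel diagonal; if no member voxel
lies in that slice the diameter is 0 and flagged.

Colocalization is the fraction of A spots sharing at least
`min_shared_voxels` voxels with B (spot set or mask). It is deliberately
asymmetric: "fraction of FISH spots at protein foci" and its converse are
different quantities. Group comparison uses the independent two-sample
*t* test, Welch by default (no equal-variance assumption); Student's
pooled variant is available. Both-groups-constant input is flagged
undefined rather than reported as p = 1.

Accuracy is digitization-limited: surface voxel centers lie up to half a
voxel inside the analytic surface, so distances on phantoms are recovered
within one voxel diagonal (≈ 1.09 µm at the default anisotropy, dominated
by dz); refining the grid tightens this proportionally.

## Image phantoms

Phantoms contain a filled ellipsoidal nucleus (default semi-axes
8 × 10 × 10 µm, the scale of polyploid nurse-cell nuclei) and isotropic
Gaussian spots (σ = 0.6 µm, the scale of a diffraction-limited FISH
signal) at chosen physical centers, plus optional i.i.d. Gaussian noise.
The truth table records each center's analytic distance to the ellipsoid
surface, obtained by 1-D Brent root finding on the projection equation
f(t) = Σ (aᵢpᵢ/(aᵢ² + t))² − 1 over the principal bracket
(−min aᵢ², 0]; exact-zero components are perturbed by 10⁻¹² aᵢ to stay on
that branch, the exact center short-circuits to min aᵢ, and the solver
matches the spherical closed form R − ‖p − c‖ to better than 10⁻⁶ µm
(tolerance of the root itself ~10⁻⁹). `place_point_at_distance` inverts
the measure along a ray, which is how test phantoms plant spots at exact
surface distances. Phantoms do not simulate a PSF, photobleaching, or
chromatid morphology; recovery tests validate the measurement chain, not
microscope realism.

## Pipelines, determinism, problem sizes

The two assembled pipelines (`run_cluster_report`,
`run_position_report`) embed a sha256-derived hash of the run config and
the package version in every output file; logs (with timestamps) go to
stderr only, so outputs of identical configs are byte-identical — the
determinism contract the tests enforce. Input errors raise a dedicated
exception mapped to exit code 2 by the CLI; unexpected failures exit 3.

Test and acceptance problem sizes are chosen as the smallest scales at
which the planted effects are statistically unambiguous: 20,000 piRNAs
for the headline ping-pong recovery (z(10) ≫ 1.96 at pairing fraction
0.5), 10,000 reads for binomial-tolerance recovery of 1U and class
fractions, 500 reads × 3 × 2-kb references for mapper oracle equality,
100 random interior points for the exact distance oracle, and 15 nuclei
per group for the two-group comparison (planted 1 µm vs 4 µm separation,
far beyond the ~0.5 µm digitization scatter).
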