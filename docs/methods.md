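# Methods

## Model

The distance between two proteins is derived from a global alignment of
their per-site feature profiles rather than of their residues. The premise
is that for remote homologues (superfamily level, low sequence identity)
the evolutionary signal survives in the *profile* of residues tolerated at
each position and in the local structure, long after the specific residues
have drifted apart.

### Raw features and the feature profile

Each site carries 23 raw dimensions: 20 amino-acid occurrence
probabilities (from the weighted-observed-percentage columns of a
PSI-BLAST ASCII PSSM, divided by 100 and renormalized), one
secondary-structure state in {H, E, C}, and one accessibility state in
{B, E}, with B assigned when the relative accessible surface area is
strictly below 0.20. The percentage columns are used rather than a
softmax of the log-odds columns because they are the file's direct
estimate of occurrence probabilities; all-zero rows (which PSI-BLAST
emits for positions with no aligned homologues) fall back to a one-hot on
the observed residue so every row stays a probability vector.

Site *i* of the profile concatenates two probability blocks:

1. **Pair block (400)** — the flattened outer product of the probability
   vectors at sites *i* and *i+1*: the joint distribution of ordered
   residue pairs at adjacent sites, which is where the correlation between
   neighbouring sites enters.
2. **Structure block (240)** — indicator of the joint accessibility state
   of the pair (BB/BE/EB/EE) ⊗ indicator of the secondary structure of
   site *i* ⊗ the probability vector of site *i* (4 × 3 × 20). Of the
   three ways to allocate the 4/3/20 factors across the available
   features, this one uses all three feature classes and matches the
   2-state accessibility feature spanning the two sites of the pair; the
   assignment of the SS label and probability vector to the *left* site of
   the pair is a documented convention.

Both blocks sum to 1, so every 640-vector sums to 2. The terminal site
pairs with itself, keeping the profile as long as the sequence so that
alignment coordinates address residues directly (the alternative — L−1
profile sites — was rejected for that reason).

### Alignment and distance

Site score: `S(i,j) = M_A(i)·M_B(j) + ω₁[ss match] + ω₂[acc match]`,
bounded in [0, 2+ω₁+ω₂]. Defaults ω₁ = ω₂ = 1.5, the midpoint of the
1.0–2.0 range such bonus weights are usually tuned over; both are
configurable and recorded in every run's metadata.

The global alignment uses the three-state Gotoh recursion (match M, gap
states Ix/Iy) with affine cost `d + (k−1)e` per gap run, defaults
d = −1.0, e = −0.2 — one gap opening costs roughly half a good match.
Gap opening is permitted from any state (including Ix↔Iy), which makes
the programme exactly the maximum over all monotone global alignments
scored with per-run affine costs; the test-suite verifies this against
exhaustive enumeration on small profiles. End gaps are penalized like
internal ones (a true start-to-end global alignment). Traceback
tie-breaks are fixed (M > Ix > Iy) for reproducibility.

The raw optimum `S_raw` is normalized Scoredist-style by the geometric
mean of the two gapless self-alignment scores,
`S = S_raw / √(S_AA·S_BB)`, clamped to [10⁻⁴, 1], and mapped through
`D = (1/√S − 1)/2`. The self-score upper-bounds any gapless match total,
so S ≤ 1 in practice; values within 10⁻¹² of 1 are snapped to exactly 1 so
that identical inputs give a distance of exactly 0 rather than float
noise. The 10⁻⁴ floor caps the distance at 49.5 for unalignable pairs.

### Trees and topology comparison

BioNJ agglomerates with the classical NJ Q-criterion and branch-length
formulas, but reduces the matrix with the variance-weighted average
(weight λ chosen to minimize the variance of the reduced distances,
with pair variances proportional to the distances). Ties in the
Q-criterion are broken by lexicographic cluster labels; negative branch
estimates are clamped to zero with the deficit moved to the sister edge.
On additive matrices the algorithm is exact (verified to 10⁻⁹ on random
trees); on noisy matrices it matches the reference `ape::bionj`
implementation, which one test runs as an independent oracle.

Robinson–Foulds is the symmetric difference of the non-trivial split
sets, normalized by the total split count of both trees — `2(N−3)` when
both are fully resolved; with multifurcating trees (e.g. the generator's
star-of-stars truth trees) the actual split counts are used, so a binary
estimate that recovers every clade of a multifurcating truth still has a
positive normalized RF (its extra splits are counted), with a floor
determined by the resolution mismatch rather than by error.

### Benchmark statistics

Per superfamily the within-family and between-family pair distances are
compared with a two-sided Mann–Whitney U test: exact null enumeration
when both samples have ≤ 8 tie-free observations, else the tie-corrected
normal approximation with continuity correction. RR is the fraction of
evaluable superfamilies with p < α (default 0.001); superfamilies
lacking either pair type are excluded and listed. RD averages
`(d_diff − d_same)/d_diff` over recognized superfamilies. `sfsd` is the
population (N-denominator) standard deviation of the between-family
distances. Pair distances are treated as independent observations even
though pairs share proteins — the standard pooled-test simplification,
noted here as a caveat.

TM-scores enter as data; `combine_tm` applies the length-weighted
combination `(nᵢTMᵢ + nⱼTMⱼ)/(nᵢ + nⱼ)` so the value no longer depends on
which chain normalized the score, and `tm_d0` provides the
`1.24·(N−15)^⅓ − 1.8` scale factor, clamped at 0.5 since the raw formula
is negative for short chains. Distance–TM correlation is Pearson on
pooled pairs with equal-width TM bins reporting per-bin mean and sd.

## Synthetic data: what it emulates and what it does not

The generator draws, per superfamily, an ancestor sequence; family
founders derive from it by i.i.d. per-site substitutions at the
between-family rate (0.5/site by default) and members from their founder
at the within-family rate (0.05/site), targets uniform over the other 19
residues. Pseudo-PSSM rows are `c/(c+1)` one-hot + `1/(c+1)` uniform
(c = 4, i.e. 80/20). Secondary structure is drawn for the ancestor as
geometric runs (mean 5) over {H, E, C} and rASA uniformly on [0, 1]; both
are inherited along the same ancestor→founder→member genealogy with
per-site redraws at the same between/within rates. Labels therefore carry
no dependence on residue identities, but they are conserved within
families the way predictor output is for near-identical sequences —
fully independent per-protein labels would be unrealistic (a predictor
run on two 95%-identical sequences returns near-identical labels) and
would inject pure noise through the ω bonus terms.

Default study conditions: 10 superfamilies × 3 families × 4 proteins,
lengths 60–120. These sizes keep the default test run and the acceptance
script in tens of seconds while leaving the Mann–Whitney tests enough
pairs (18 within, 48 between per superfamily) to reach p < 0.001 when the
separation is real.

What passing on this generator does **not** show: robustness to indels
(the process is substitution-only, so true alignments are gapless),
rate heterogeneity across sites, realistic substitution preferences
(no JTT-like matrix), PSSM estimation noise from actual database
searches, or correlated prediction errors in SS/rASA. Results on real
SCOP-scale data depend on those factors and on PSI-BLAST/SPIDER2 runs
that are outside this package's scope.

## Numerical choices

* PSSM rows renormalized to sum 1 (tolerance 10⁻⁶ asserted downstream);
  probability-vector inputs to the profile blocks validated at 10⁻⁴.
* rASA threshold strict: exactly 0.20 → exposed. Values are
  auto-detected as percentages when any exceeds 1.5.
* Distance-matrix symmetry enforced at 10⁻⁶ on input, then symmetrized
  exactly; diagonals zeroed. Each unordered pair is computed once, so
  `sd_distance` symmetry is exact by construction.
* PHYLIP dialect is relaxed (whitespace-delimited names up to 50 chars)
  because SCOP-style identifiers exceed the classical 10-character field.
* The Q-criterion tie-break and the degenerate all-equal-distance matrix
  both resolve deterministically (lexicographic labels).
* Profiles require L ≥ 2 (no adjacent pair exists otherwise); records
  outside the 50–500 length working range are accepted with a warning,
  since that range is a dataset screening rule, not an algorithmic limit.

## Known limitations

* Gap penalties and ω weights are not fitted; the defaults are sensible
  but the package makes no claim of optimality, which is why every run
  records them in its metadata.
* The score normalization assumes non-negative site scores (true here by
  construction); profiles with zero self-score are rejected as
  degenerate.
* BioNJ is O(N³); the all-vs-all aligner is O(N²·L²) and single-threaded.
  Thousands of pairs of 500-residue profiles are minutes of work; the
  implementation favours clarity and exactness over large-scale speed.
* `top1_homolog` and the RR/RD machinery assume the distance matrix is
  complete; missing pairs are not supported.
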