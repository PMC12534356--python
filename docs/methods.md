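# Methods

This note records the models the package implements, the defaults it
ships, and the places where a convention had to be chosen.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model and censoring

All concentrations are dissolved (filtered) phase in **µg/L** throughout
the package; the health-risk module converts to mg/L at its boundary with
an explicit 10⁻³ factor.  A measurement is either a value or a
left-censored mark `<x` (below the instrument detection limit `x`);
exactly one of the two.  Censored values are substituted only on request,
via one of four policies:

| policy    | substitute        | note |
|-----------|-------------------|------|
| `half_dl` | DL/2              | default; the convention under which the packaged dataset's published reference-site means (e.g. Co 0.03, Ni 0.05, Zn 2.45 µg/L) are reproduced exactly |
| `zero`    | 0                 | lower bound; breaks geometric-mean indices |
| `dl`      | DL                | upper bound |
| `drop`    | remove            | downstream numeric use raises, never skips silently |

Substitution is idempotent, never touches uncensored values, and leaves
the raw set intact.  Cd and Cr are carried in the data model but are
fully censored in the packaged dataset (DL 0.29 and 0.05 µg/L) and
excluded from all index computations by default.

The packaged dataset is a 19-site dry-season survey: 9 main-stem river
sites with downstream distance, 5 tributary sites, the underground mine
drainage channel, and 4 lake sites.  Two table cells whose printed source
was ambiguous are resolved in `core_data.FIXTURE_NOTES`; the resolution
is pinned by the dataset's own summary rows (reference-site means and
main-stem means), which the test suite enforces.

## Standards and index conventions

- HEI, WQI and CCME WQI use the Ugandan (UNBS) potable-water limits with
  the cobalt objective taken from the British Columbia aquatic-life
  guideline (110 µg/L), since neither UNBS nor WHO publishes one.  WHO
  limits are registered and selectable.
- The WQI weight sum is always computed from the weights map (the default
  1–5 toxicity weights sum to 37), and pH enters as a plain ratio against
  its upper objective (9.5).  Both are overridable via `WQIScheme`.
- CCME WQI follows the standard three-factor form; pH is tested against
  both bounds of its range (excursion `value/upper − 1` above,
  `lower/value − 1` below).  The model minimum of 4 parameters × 4 tests
  is enforced.  Values at exactly a limit count as *not* exceeded (strict
  inequality), in both CCME failure tests and exceedance summaries.
- PLI is computed as `exp(mean(log CF))` for numerical stability; tests
  verify equivalence with the direct n-th-root product.
- Classification bands follow the printed conventions of each index;
  where sources print open/closed bounds inconsistently, left-closed
  intervals are used (so PLI = 1 is "moderate", PERI = 150 is
  "moderate", Er = 40 is "moderate").  A CCME value of exactly 95 is
  classed "good".
- Background Cb is the per-PEM arithmetic mean over reference sites
  (default: the upstream site and the cleanest confluence site,
  NY-01/NY-13, under `half_dl`).

## Ecological risk

Er_i = Tr_i × CF_i with CF formed from the **mean** concentration over
the assessment scope (warning below five sites, per the method's rule);
PERI = Σ Er_i.  The default toxic-response factors are the classical
ones: Al 5, As 10, Cd 30, Co 5, Cr 2, Cu 5, Fe 1, Mn 1, Mo 15, Ni 5,
Pb 5, Zn 1.  Default scope is the 9 main-stem sites; tributaries, the
mine channel and the lake are excluded unless requested.

## Health risk

Doses:

    CDD = C·IR·ED·EF/(AT·BW)
    DAD = C·Kp·ED·EF·ET·SA·10⁻³/(AT·BW)

The 10⁻³ L/cm³ factor converts the water film implied by
Kp (cm/h) × SA (cm²) × ET (h) into litres; the governing equation is
often printed without it, which inflates dermal doses a thousand-fold.

Averaging time is an explicit per-scenario field.  The default for
*both* modes is AT = ED × 365 d, i.e. cancer risk is averaged over the
exposure period rather than a fixed 70-year lifetime.  This is the
package's deliberate choice: it is how this strand of the water-risk
literature applies the equations in practice, and it preserves the
expected cohort ordering (child > adult for every HQ and CR, because the
child's IR/BW and SA·ET/BW ratios are higher) that the fixed-lifetime
convention would invert (adult ED 30 y vs child 6 y would dominate).
Setting `AT_cancer=70*365` on a scenario restores the fixed-lifetime
convention.

Cohort defaults are US-EPA RAGS residential values — child: IR 1 L/d,
ED 6 y, EF 350 d/y, BW 15 kg, ET 1 h, SA 6600 cm²; adult: IR 2 L/d,
ED 30 y, EF 350 d/y, BW 70 kg, ET 0.58 h, SA 18000 cm².  The toxicology
table (Kp, oral RfD, gastrointestinal absorption fraction, oral slope
factor) is seeded from IRIS/RAGS values commonly used for these
elements and is explicitly an *editable default*, not a transcription of
any particular study's supplementary tables: absolute HQ/HI/CR
magnitudes move with these parameters, so the package's tests assert
decompositions (HQ = HQ_ing + HQ_dermal, HI = ΣHQ, CR = ELCR_ing +
ELCR_dermal), linearity in concentration, and cohort/element orderings
rather than absolute risk values.  Slope factors are present only for
As, Ni and Pb; requesting cancer risk for any other element raises.
RfD_ABS = RfD_ing × ABS_g and CSF_ABS = CSF_oral/ABS_g are always
derived, never stored.

## Source apportionment

Variables are z-scored (sample SD).  Suitability diagnostics: overall
KMO from the anti-image partial correlation matrix (for two variables
KMO is identically 0.5) and Bartlett's sphericity test,
χ² = −(n−1−(2p+5)/6)·ln|R| on p(p−1)/2 df.  Components are extracted
from the correlation matrix, retained by the eigenvalue-1 rule, scaled
to loadings (eigenvector × √eigenvalue), and rotated by varimax with
Kaiser normalisation (tolerance 1e-6, 100-iteration cap).  Rotation
preserves per-variable communalities to 1e-8 (tested).  Signs are fixed
so each factor's largest-magnitude loading is positive, and factors are
ordered by rotated explained variance, making loading tables
deterministic.  Loadings are labelled strong (> 0.75), moderate
(0.50–0.75) or weak (< 0.50); display tables may blank magnitudes below
0.3 while the full matrix is retained.

Clustering is agglomerative with between-groups average linkage (UPGMA).
The default dissimilarity is **squared** Euclidean distance — the
convention of the statistical packages this analysis is traditionally
run in, and the one under which the packaged dataset's two heavily
contaminated sites (the mine channel and the ore-plant tributary)
separate as singletons at the conventional (D_link/D_max)×100 < 10 cut;
plain Euclidean distance is available via `metric="euclidean"`.  Merge
heights are reported raw and rescaled to (D_link/D_max)×100; dendrograms
export to Newick.

Default analysis scope is the 15 non-lake samples × the 10 quantified
PEMs (pH excluded from the multivariate analysis; Cd/Cr excluded as
fully censored), with censored cells at DL/2.

## Synthetic data

The generator is a pure function of its config (including the seed).
Main-stem sites are spaced evenly along the reach (default 9 sites over
16 km, matching the survey layout); tributary sites carry plain
background.  Noise-free truth is background × the product over sources
of `1 + (m − 1)·exp(−Δd/λ)` for sites a distance Δd ≥ 0 downstream of
each source.  Observed values multiply truth by lognormal(0, σ) noise
per cell and are emitted censored when below the element's detection
limit.

Defaults are chosen to emulate the packaged survey and are fixed:
background = the derived reference profile; one mine-drainage-like
source at km 2.5 with multipliers 2×10⁴ (Co), 2×10³ (Ni), 150 (Cu),
25 (Mn), 20 (Zn) — the order of enrichment observed at mine-proximal
sites; attenuation length λ = 5 km (partial recovery by the end of the
16 km reach, as observed downstream); σ = 0.3 (moderate field
variability for dissolved metals); detection limits = the survey's
instrument DLs.  The generator reproduces the *structure* of real
mining-affected data (right-skewed positive concentrations, downstream
decay, censoring of clean-site values); it does not model hydrodynamic
transport, seasonality, inter-element correlation beyond shared
sources, or pH variation — so passing recovery tests demonstrate index
and factor-model correctness under the stated mechanism, not
hydrological realism.

`recover_check` verifies that source-influenced sites out-rank
background sites on PLI and reports each element's dominant varimax
factor; `source_recovery_rate` measures, over seeded replicates of a
two-source scenario (30 sites, σ = 0.1), how often the two source
element groups land on distinct factors.

## Numerical and degenerate-input conventions

- Geometric means in log space; any CF ≤ 0 is an error (cannot occur
  under `half_dl`).
- Singular correlation matrices make KMO/Bartlett an error when called
  directly, and NaN (with the component solution still returned) inside
  `pca_varimax`, where perfect collinearity is a legitimate input.
- Zero-variance columns are rejected by `standardize` with the column
  named.
- Identical cluster items merge at height 0; an all-zero dendrogram
  rescales to 0 rather than dividing by zero.
- Empty sample sets: loading an empty table is valid; taking a mean
  profile of one is an error; subsetting to an empty group warns.

## Known limitations

- The WQI's published per-site values in the source study are not exactly
  recoverable (its stated weight sum disagrees with its printed weights);
  the package computes the self-consistent form and matches at
  band level, with the uncontaminated-site value agreeing numerically.
- One published index cell (the NY-11 PLI) is internally inconsistent
  with the published concentrations and is not reproduced; see the test
  suite's documentation of that comparison.
- Health-risk magnitudes depend on the editable exposure/toxicology
  defaults; only structure (orderings, decompositions, linearity) is
  guaranteed.
- No sediment-phase risk index, no soil/dust/food or inhalation exposure
  routes, no probabilistic (Monte-Carlo) risk, no hydrological modelling,
  no seasonal aggregation.
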