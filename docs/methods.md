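# Methods

## The question and the quantities

Given a rooted phylogeny of a regional species pool and a chronological
series of local assemblages (which species were present in each sample
unit), the package asks, unit by unit: are the co-occurring species more
closely related than chance (phylogenetic clustering, the signature of
environmental filtering), less related (overdispersion, the signature of
competitive exclusion or convergence), or neither? And then: does the answer
itself drift, cycle, or persist over time?

Relatedness is measured on topology alone. The distance between two tips is
the number of edges on their tip-to-tip path ("node-count" distance, i.e.
path length with every branch length set to one). Two observed statistics
summarize each assemblage of richness >= 2:

* **MPD** — mean pairwise distance over all unordered pairs of present
  species; sensitive to tree-wide structure.
* **MNTD** — mean, over present species, of the distance to the nearest
  present relative; sensitive to structure near the tips.

Each is standardized against a null distribution obtained by randomizing
the community matrix:

    NRI = -(MPD_obs  - mean MPD_null)  / sd MPD_null
    NTI = -(MNTD_obs - mean MNTD_null) / sd MNTD_null

The sign flip makes clustering positive. Significance is **not** read from
the Gaussian scale of the SES: each unit's observed value is located in its
empirical null distribution by mid-rank, `rank = (#null < obs + 0.5 #null =
obs) / n_rand`, and classified clustered if `rank <= alpha/2`, overdispersed
if `rank >= 1 - alpha/2`, else random (alpha = 0.05 two-tailed by default).
The rank test is exact under the null model's exchangeability and is robust
to the null distributions' skew at low richness.

### Node counting convention

"Number of nodes separating two species" is ambiguous (internal nodes on the
path vs edges on the path). This package counts **edges**; counting internal
nodes would subtract exactly 1 from every pairwise distance, an affine shift
that cancels in the standardization of both MPD and MNTD, so the choice
cannot change any SES, rank, or pattern — only the raw distances.

### Guild submatrices

Guild analyses restrict the community matrix's columns to one trophic guild
but keep the **full-tree** distance submatrix rather than re-deriving
distances on a pruned guild tree. Pruning collapses internal nodes and
changes node counts; using one fixed tree keeps a single evolutionary
reference frame across guilds. The guild's species pool is every guild
member captured at least once over the whole study; rows (units) are kept
even when the guild is absent from them, then dropped as degenerate
(richness < 2) with their labels logged so series keep gaps at the right
chronological positions.

## Temporal scales

One set of capture records is aggregated three ways, each row chronological:

| scale            | unit                                  | fixture units |
|------------------|---------------------------------------|---------------|
| `sample`         | one sampled (year, month)             | 117           |
| `calendar_month` | one calendar month pooled over years  | 12            |
| `year`           | one year (12 months pooled)           | 10            |

Presence is idempotent under record duplication, and pooling can only add
presences. Abundances are collapsed to presence–absence before analysis: the
null models are binary-matrix nulls and the indices unweighted; counts exist
in the record format only for realism.

## Null models

* **independent_swap** (primary): a Markov chain on binary matrices. Each
  trial draws 2 distinct rows and 2 distinct columns uniformly; if the 2×2
  submatrix is a checkerboard its diagonals are exchanged, else nothing
  happens. Both marginals (unit richness, species frequency) are conserved
  exactly; the chain is symmetric and aperiodic, hence uniform over the
  connected fixed-marginal set. The whole matrix is randomized jointly and
  per-unit statistics are read off each retained matrix — that is what a
  fixed-fixed matrix null means. Defaults: burn-in = 10·(rows·cols) trial
  swaps, thinning = rows·cols trial swaps between retained samples, the
  standard prescription for fixed-fixed chains; the test suite verifies
  chain uniformity against exhaustively enumerated fixed-marginal sets at
  exactly these defaults.
* **taxa_labels**: permutes the distance-matrix labels over the analysis
  pool, communities fixed.
* **richness**: refills each row with its observed richness uniformly among
  columns (row sums kept, column sums free).
* **frequency**: refills each column with its observed frequency among rows.

`n_rand` defaults to 10000; the test suite and the acceptance script use 999
as their desk-scale problem size. Degenerate situations are reported, not
hidden: units of richness < 2 and units whose null distribution has zero
spread (e.g. membership forced by the marginals) are classified `undefined`
and excluded from pattern denominators, with counts reported.

The swap chain and the per-row MPD/MNTD evaluations are numba kernels with
an internal xorshift64* generator; given a seed, null streams — and hence
every output table — are bit-reproducible across runs and platforms.
Pure-Python reference implementations of every statistic remain in the
public API and the kernels are tested against them.

## Serial runs test

Each (group, scale, index) series of SES values, in chronological order, is
dichotomized around zero — the theoretical null center of an SES, so +/−
mean clustered-side/overdispersed-side — or optionally around the series
median; exact ties are dropped. Gaps (dropped or undefined units) are
removed and the remaining signs concatenated, a logged caveat: the runs test
has no standard missing-data treatment and imputation would fabricate
serial structure.

With `n_plus` and `n_minus` signs and `u` observed runs (maximal same-sign
blocks), the exact conditional distribution of the run count under random
arrangement is

    P(U = 2k)   = 2 C(n+−1, k−1) C(n−−1, k−1) / C(n, n+)
    P(U = 2k+1) = [C(n+−1, k−1) C(n−−1, k) + C(n+−1, k) C(n−−1, k−1)] / C(n, n+)

The reported p-value is the tail probability in the direction of the
observed departure, `min(P(U <= u), P(U >= u))`: both directions (too few
runs = persistence, too many = alternation) can trigger, and the realized
size at nominal alpha = 0.05 is about 0.056 on length-20 iid sequences (the
suite measures it), i.e. the convention is anti-conservative by at most a
factor of two relative to a doubled-tail convention. For n > 20 a
continuity-corrected normal approximation with E[U] = 2n+n−/n + 1 and the
standard runs variance replaces the exact tail; the worst-case discrepancy
at n+ = n− = 50 is below 0.02. Series with all signs on one side are
reported untestable, never silently skipped. The 12-unit calendar-month
series is cyclic (December adjoins January) but is treated as a linear
sequence, matching common practice.

## Synthetic campaign generator

No field data ship with the package; the generator emulates the sampling
design the analysis expects so that every stage is exercised end to end.

* **Tree**: Yule topology grown by splitting a uniformly chosen extant tip;
  151 tips by default; all edge lengths 1.
* **Campaign**: 10 years × 12 months minus 3 missed months = 117 sampled
  units, missing months seed-chosen subject to no calendar month or year
  being lost entirely.
* **Guilds**: six diet guilds of sizes 23/11/24/15/23/33 (piscivorous,
  carnivorous, invertivorous, herbivorous, detritivorous, omnivorous),
  remainder unclassified; assigned to consecutive blocks of tips in tree
  order by default so guilds are phylogenetically cohesive (random
  assignment available for null checks).
* **Occupancy**: per-species baseline occupancy drawn Beta(1, 2) — a
  right-skewed occupancy distribution (many infrequent species, a few
  ubiquitous ones) giving ~50 of 151 species in a typical month. Every
  species is guaranteed at least one capture over the campaign (the analysis
  pool is the observed species list); a species missed by all draws is
  injected into one random sampled month.
* **Counts**: shifted-geometric (>= 1); never used beyond presence.

Assembly regimes (trait = Brownian motion on the tree, unit variance per
edge, root 0):

* **neutral** — independent Bernoulli occupancy; communities random with
  respect to phylogeny by construction. This is the calibration fixture: at
  999 randomizations across >= 100 units, NRI/NTI means sit within ±0.15 of
  0, SDs within [0.8, 1.2], and two-tailed rejection at alpha = 0.05 inside
  the exact binomial 99% envelope.
* **filtering** — monthly environment `E_t = A sin(2π month/12) + noise`,
  occurrence probability ∝ baseline × exp(−(trait − E_t)²/(2σ²)),
  renormalized to the neutral expected richness. Two numerical choices
  matter and are deliberate: the seasonal amplitude default (4.5 ≈ 1.9× the
  trait SD at 151-tip Yule depth) makes the environmental state sweep the
  whole niche axis, because a fixed-fixed null absorbs any *time-invariant*
  filter into the column marginals — without seasonal turnover there is
  nothing for the null to detect; and the renormalization (the "∝") keeps
  monthly richness near neutral levels, since a handful of species per unit
  gives MPD too much sampling noise for any pattern to reach significance.
  Default σ = 1.0 (~40% of the trait SD).
* **repulsion** — species admitted sequentially in random order; a
  candidate's admission probability is multiplied by
  `min_j (1 − exp(−d(s,j)/σ))` over already-admitted j, with d the
  node-count distance. Note the strength direction: σ → 0 makes the factor
  → 1 for all d >= 2 (the neutral limit), and larger σ penalizes close
  relatives more strongly while also suppressing richness. Default σ = 5.0,
  the typical nearest-relative distance among species co-occurring at the
  fixture's monthly richness, so exclusion discriminates exactly at the
  scale MNTD measures.

At these defaults (fixture seed 1, null seed 7, 999 randomizations) the
filtering regime raises the proportion of NRI-clustered monthly units by
≈ 0.42 over neutral and the repulsion regime raises NTI-overdispersed units
from ≈ 0.01 to ≈ 0.16 — the acceptance suite asserts a ≥ 0.3 gain for
filtering and a strict increase for repulsion.

### What the generator does not emulate

Flood-pulse hydrology, dispersal and colonization dynamics, gear-specific
catchability, abundance structure beyond presence, and detection error. A
passing suite therefore demonstrates that the *method* is correct and
calibrated and that it recovers known assembly signals of realistic
strength — not that any particular field system will show such signals, nor
how strong real filtering/exclusion effects are.

## Numerical and degenerate-input choices

* Ranks use mid-rank for ties with a 1e-9 absolute tie tolerance on the
  distance statistics (tied null draws are common under the swap null, where
  compositions recur).
* Null mean/SD use only valid (richness >= 2) null draws per unit; this
  matters for the frequency null, which does not conserve row sums.
* Degree-2 internal chains are collapsed on tree ingest; polytomies are kept
  and treated literally (tips of a polytomy are mutually 2 edges apart).
* Per-(group, scale) analyses derive independent sub-seeds from the run seed
  via `numpy` SeedSequence spawn keys, so adding a group never perturbs
  another group's null stream.
* Output tables are written with a fixed float format; identical config +
  seed gives byte-identical files.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run the full 117 × 151 analysis
grid at 999 randomizations (the package default stays at 10000), exhaustive
oracles up to n = 12 (runs test), 10-tip subsets of sizes 2–8 (metrics), and
4×4 enumerable fixed-marginal sets (chain uniformity).
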