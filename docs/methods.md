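# Methods

`delbench` evaluates how well ultrahigh-throughput virtual screening
(uHTVS) recovers the hits of a DNA-encoded library (DEL) selection. This
note documents the statistical models, the conventions behind every
numerical choice, and what the synthetic benchmark does and does not
show about real campaigns.

## Combinatorial libraries

A DEL is modelled as an ordered list of positions, each holding a list
of building-block fragments. The library size is the product of the
position cardinalities; enumeration streams compounds in lexicographic
order of the index tuple, so output is stable byte-for-byte across runs.
Compound identifiers are zero-padded per-position indices joined by
hyphens (`003-087-112`): sortable, human-readable, and a bijection of
the tuple. Real DEL decks carry opaque vendor identifiers; nothing in
the analysis depends on the identifier scheme beyond bijectivity.

Chemical assembly uses single-atom wildcard attachment markers with
atom-map numbers (`[*:n]`). Each map number must occur on exactly two
wildcards across the chosen fragments; the pair is fused into a single
bond and the product canonicalized with RDKit. This covers linear
chains and scaffold topologies with one mechanism. Count-only mode
skips assembly entirely, so billion-scale spaces are handled
arithmetically; full enumeration is intended for libraries up to ~10^7
members (a 107,616-compound library assembles in about half a minute on
one CPU).

Duplicate compounds — distinct index tuples with identical canonical
SMILES, which happens when a vendor deck repeats a fragment — are kept
as separate rows (their experimental read counts differ even when their
structures do not) and reported alongside a unique-compound count.

## Hit calling from read counts

The normalized fold number Fn of a compound is

    Fn = lower95(after) / total_after
         ---------------------------------
         upper95(before) / total_before

where `lower95`/`upper95` are exact (Garwood) Poisson confidence limits
computed from chi-square quantiles, two-sided at 95% (2.5% per tail,
configurable). The exact limits are the standard conservative choice;
whether the original analysis used one- or two-sided bounds is not
documented, so the two-sided convention is fixed here and stated.
No pseudocount is added: a zero after-count gives Fn = 0, which keeps
Fn monotone in the counts (strictly increasing in the after-count,
strictly decreasing in the before-count). Compounds with Fn ≥ 1.0
(boundary inclusive) are on-DNA hits; alternatively a minimum-copies
rule flags compounds whose raw post-selection read count reaches a
threshold, as used for decks distributed without control counts.

## Ranking metrics

Compounds are ranked ascending by docking score (an energy-like value,
lower = better) or descending by the virtual-hit-likeness value VHL in
[0, 1]. Ties are broken by compound id for a deterministic permutation.

ROC curves process tied scores as a block (one diagonal segment), so
the complete-curve area equals the Mann–Whitney U statistic normalized
by the number of positive–negative pairs; this identity is asserted to
1e-12 in the tests against `scipy.stats.mannwhitneyu`. Compounds that
failed to dock are excluded from the curve but retained in the
positive/negative denominators: the curve then stops short of (1, 1)
and its unrescaled trapezoidal area is reported as a partial AUC
(pAUC). Truncation, not worst-rank imputation, is used because an
undocked compound carries no rank information; imputing it last would
manufacture one.

The enrichment factor uses the recovered-hit formulation

    EF = (hits_in_top / total_hits) / (selected / population)

with the population defaulting to the whole library including undocked
members. Recall, precision and F1 are the usual set-based definitions;
an empty prediction set has precision 0 (with a warning) and F1 is 0
when precision + recall is 0. The iterative surrogate-docking budget is
`per_cycle x cycles + 2 x per_cycle` (the first cycle docks three
batches: training, test and validation).

Known discrepancy: published AurA enrichment values for the
VHL-selected decks (0.745 at 50k and 2.608 at 1M) are not reproducible
under this EF formulation with any stated library size, while the MAPK
value (0.057) reproduces exactly; the formulation follows the
reproducible case and the discrepancy is documented rather than
resolved.

## Building-block statistics

For a block fixed at one position, the subset S holds every compound
containing it there; P_bind is the hit fraction of S. Because absolute
P_bind scales with the campaign's overall hit rate, comparisons use
range-scaled values, normalized to [0, 1] **within each position**
independently — positions have different cardinalities and subset
sizes, and cross-position scaling would conflate them. A degenerate
position (all blocks equal) maps to all zeros. The compatible-partner
count CP of a fixed block is the number of distinct partner blocks
co-occurring with it among hits, summed over non-fixed positions;
CP_max is the sum of non-fixed cardinalities. Scaffold positions are
ordinary positions. Docking-based "computational hits" are the top-N
ranked compounds, fed through the same machinery.

## Exit-vector accessibility

The exit vector of a pose is an ordered ligand atom pair (base,
terminal) whose unit direction points where the DNA tag must leave. The
accessibility score is the repulsive potential

    B = sum_j  A * max(cos theta_j, 0) / r_j^n

over protein atoms j within a cutoff of the terminal atom, with r_j the
terminal-to-atom distance (Å), theta_j the angle between the exit
direction and the terminal-to-atom line, A = 1e9 and n = 6 by default.
The angular factor is the cosine clamped at zero: atoms behind the exit
vector cannot block the tag, which is what makes B = 0 mean "the tag
can occupy the opening". The cutoff (default 10 Å) exploits the r^-6
decay — an atom at 10 Å on-axis contributes 1e3 versus 1.6e7 at 2 Å —
and is configurable. B < 1e-9 is treated as exactly 0 for the
feasibility flag to absorb floating-point sums. With several candidate
exit vectors the lowest-B one is retained (ties to the lowest index).
Hydrogens are scored when present in the structure; a heavy-atom-only
toggle exists. B is invariant under rigid motions of the whole system
(asserted to 1e-9 on random rotations/translations).

## Synthetic benchmark

The generator plants ground truth so every stage's recovery is testable
without external data.

* **Affinity** is additive over blocks: each block draws a N(0, 0.25)
  background contribution (sd 0.5) and one planted block per position
  gains +3.0. Additivity is precisely the premise that makes P_bind/CP
  analysis meaningful, so planted-signal recovery is well defined.
* **Read counts** are Poisson. Pre-selection rates are uniform at
  `sequencing_depth / n`; post-selection rates are proportional to
  `exp(s * affinity)`, with s calibrated by root finding so the
  strongest binder is enriched `selection_depth`-fold (default 100x)
  over the average compound. The achievable maximum is n / #maxima;
  unreachable requests are clamped with a warning. Totals are the
  realized column sums, as in real sequencing data.
* **Docking scores** follow a Gaussian copula against affinity with
  correlation rho (default 0.8): the latent score is
  `-(rho * z + sqrt(1 - rho^2) * eps)` with z the normal score of the
  affinity rank. rho = 1 inverts the affinity ranking exactly and
  rho = 0 is independent; between, the Spearman correlation is
  (6/pi)·asin(rho/2). A Bernoulli `undocked_fraction` drops scores;
  VHL values are the empirical CDF of a noisy monotone transform of the
  latent, so they live strictly inside (0, 1).
* **Pocket** geometry is a Fibonacci-sphere shell of pseudo-atoms
  (default radius 7 Å, 400 points) with the polar cap above the opening
  half-angle (default 95°) removed. Exposed poses aim the exit vector
  along +z from the axis: with the opening past 90°, every wall atom is
  strictly behind the vector, so B = 0 holds as a geometric identity,
  not a tolerance. Buried poses aim at the far wall, which sits inside
  the default cutoff, so B > 0 is likewise guaranteed. The buried count
  is deterministic (`round(fraction * n_poses)`), making the feasible
  ratio an exact complement of the configured fraction.

Default library shape is 12 x 16 x 18 = 3,456 compounds: large enough
for top-1,000 analyses and stable block statistics, small enough that
full enumeration and forty-seed sweeps run in seconds.

What the synthetic data does **not** emulate: sequencing-error and PCR
artefacts beyond Poisson noise, chemically meaningful docking energies,
non-additive (synthon-interaction) binding, protonation/stereochemistry
expansion, and real pocket shapes. Passing recovery tests therefore
demonstrates correctness of the analysis pipeline under its own model
assumptions, not performance claims about any particular real screen.

## Numerical conventions

* Thresholds are boundary-inclusive throughout (Fn ≥ t, copies ≥ k,
  VHL ≥ t, top-N includes rank N).
* Quantiles in the five-number summary use linear interpolation
  (`numpy.quantile` default).
* All randomness flows through `numpy.random.default_rng` seeded from a
  single integer; independent streams are derived as `[seed, stream]`
  seed sequences, so results are platform-independent and
  bit-reproducible.
* Monte-Carlo checks use 3-standard-error bands; sample sizes are
  chosen so the Monte-Carlo resolution is comparable to the quantity's
  discreteness (e.g. the null enrichment factor of a 10% selection
  moves in steps of 0.1 and is averaged over 400 seeds).

## Limitations

* The pAUC integration convention (unrescaled trapezoid of the
  truncated curve) and the per-position P_bind normalization are
  documented choices; other software may rescale or normalize globally.
* The enumeration order and identifier scheme are repo conventions, not
  reproductions of any vendor tool's output.
* Accessibility scoring consumes coordinates only; it does not model
  the linker or tag explicitly, and it is a pose filter, not a
  re-scoring function.
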