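# Methods

This note records the model as implemented, the defaults and why they were
chosen, the numerical choices, and the limits of what the synthetic inputs
and tests can show.

## Model structure

The chain is: energy imparted ε → event multiplicity `J_TOT = ⌊ε/ε_th⌋` →
multinomial event types (A: direct strand break, B: OH radical, C: direct
base damage, D: inert) → operator algebra turning break-producing events
into a distribution over lesion classes → marginals, and optionally a fold
with an energy-imparted frequency spectrum dF/dε for per-Gy yields or
per-particle cross-sections.

A key exact factorisation drives the implementation: the base-damage and
inert branches of a B event never touch the strand-break state, so the
spectrum of any event composition equals the *pure-break* spectrum `A_n`
at its total break count n, weighted by a binomial in r₁ for the B events'
break successes, with an independent base-damage shift.  At fixed `J_TOT`
in exact mode every event is i.i.d. trinomial — break with
`p_A + p_B·r₁ = 0.226`, base damage with `p_C + p_B·r₂ = 0.304`, nothing
otherwise — and the full mixture over compositions is a closed-form weight
map over (breaks, base damages) applied to the cached `A_n` chain.  This
makes `J_TOT = 60` cost well under a second after a few seconds of one-time
chain construction.

## Clustering algebra

When the k-th break is added it is isolated with probability `q₀(k)` or
attaches with `2q₁(k) = 1 − q₀(k)`, the two strands equally likely.  The
attachment weight is distributed **equally over the existing break-bearing
lesions** (not proportionally to their break counts): this is the
convention under which the second-, third- and fourth-order closed-form
expansions — including the fourth-order `q₀q₁²` tier coefficients
(6, 2, 2, 1, 1) and the `q₁³` tier's 7 : 1 split between DSB(++) and the
four-break same-strand chain — are all reproduced exactly, and it is
confirmed independently by the base-pair-level Monte-Carlo simulator.
Upgrade rules on attachment: SSB-class targets split equally between the
same-strand (SSB(+) → SSB(++) → grouped) and opposite-strand
(→ DSB class) outcome; any DSB-class target simply deepens
(DSB(S) → DSB(+) → DSB(++), absorbing).

The ladder `q₀(2..7) = 0.87, 0.74, 0.60, 0.475, 0.35, 0.12` for 73 bp with
a 10 bp window is treated as normative input.  For k ≥ 8 it is extended
linearly and clipped at zero (it reaches zero exactly at k = 8), matching
the expectation that essentially every further break joins an existing
cluster.  `q₀(1) = 1` always.  A constant-q₀ mode exists because the
closed-form expansions are written with symbolic q₀; all coefficient tests
run in that mode.

### Exact vs `paper_approx` mode

The default propagation is numeric and exact at every order.  The
`paper_approx` mode mirrors the truncations that make the high-order terms
tractable in closed form:

* products of three or more B factors keep strand-break terms only to
  second order in r₁ (the dropped r₁³⁺ weight moves to the inert branch);
* from the fifth break onward, a state already carrying two or more
  attachments routes its whole attachment weight to its most complex
  lesion (with the usual same/opposite split), so cubic and higher
  attachment powers are tallied into the DSB(++) and grouped-SSB classes.

The two modes agree to < 0.3 % total variation for `j_tot ≤ 4` by
construction, and differ materially only where many breaks occupy the
segment.  The tally concentrates late attachments in one cluster where the
exact per-lesion rule spreads them; as a consequence the grouped complex
class saturates earlier in approx mode.  The package's qualitative
statement that DSB(++) becomes the leading DSB category once more than six
breaks occupy the segment is a property of this tallied, break-resolved
picture; in the exact per-lesion propagation the crossover sits near ten
breaks, and in the full multinomial mixture (where only 0.226 of events
produce breaks) it requires correspondingly larger `J_TOT` (≈ 50, i.e.
~0.9 keV imparted — reached by direct ion traversals but not by sparse
tracks).  Both pictures are exposed; the reported tables always state
their mode.

## Monte-Carlo oracle

`mc_oracle` re-derives the algebra by brute force: breaks are placed at
explicit base-pair positions and strands, lesions are the connected
components of breaks within the window, a component is DSB-class iff it
contains an opposite-strand pair within the window, and complexity follows
the component's break count.  Placement conventions:

* `uniform-bp` / `site-resolved` — position uniform on the segment, strand
  fair coin (re-hits of an occupied site collapse: a strand cannot be more
  broken).  Used for q₀ estimation.  Note this convention gives
  q₀(2) ≈ 0.73 on 73 bp/10 bp — visibly different from the ladder head
  0.87, which is why the printed ladder, not an estimate, feeds the
  algebra.
* `table-calibrated` — uniform placement with the integer window whose
  analytic two-break isolation probability is closest to the ladder head
  (window 4 for 0.87 on 73 bp).
* `ladder-matched` — the isolate-vs-attach decision is drawn from the q₀
  ladder; the position is then placed by rejection sampling (isolated:
  beyond the window of every break; attached: the strand is committed by a
  fair coin first, then a position within the window of a uniformly chosen
  lesion and clear of all others).  Committing the strand before the
  position rejection keeps the same/opposite split exactly ½ regardless of
  edge effects and site occupancy.  Classification remains purely
  geometric, so this convention simulates exactly the stochastic process
  the algebra propagates and is its independent oracle: at 10⁶ trials per
  composition, every joint lesion state of every composition with
  `j_A + j_B ≤ 4` agrees with the algebra within three binomial standard
  errors.

The trial loop is numba-compiled; one seeded generator per call, no global
state, fixed seed ⇒ bit-identical output.

## Spectra and folding

Spectra are stored on an explicit energy grid with trapezoid normalization;
readers renormalise deviations under 1 % and reject anything worse, naming
the offending line.  The parametric generator uses the exponential
integral form `F(>ε) = exp(−ε/ε₀)` appropriate for low-LET electron
spectra at this site size.  The bundled presets are synthetic exponential
stand-ins labelled by the radiation quality they emulate (ε₀ = 45 eV for
100 keV-electron-like up to 380 eV for slow-carbon-like); they exist so the
pipeline runs end-to-end without external data and are **not** fits to
published Monte-Carlo spectra — quantitative yield comparisons require the
real spectrum for the radiation as an input file.  Real low-LET spectra
carry more weight at both very low and very high ε than a single
exponential, so the presets understate complex-DSB yields.

The site mass defaults to a 5 nm × 5 nm right cylinder of unit-density
material, 9.82 × 10⁻²³ kg; the frequency-mean specific energy per event is
`z̄_F = ⟨ε⟩·(1.602 × 10⁻¹⁹ J/eV)/mass` (≈ 7.3 × 10⁴ Gy per event for the
electron-like preset — single events in nanometre sites deposit enormous
local doses).  The per-Gy conversion is `c = 10⁹/(n_BP·z̄_F)`: `1/z̄_F`
events per site per Gy times `10⁹/n_BP` sites per Gbp.  The cross-section
expression implements `10⁹·n_BP·z̄_F/(6.24·LET)·∫(dF/dε)P_j dε` with z̄_F
in Gy and LET in keV/μm; because the dimensional grouping of the 6.24
fluence–dose–LET constant is not closed, an audited alternate grouping
(multiplying rather than dividing by 6.24) is selectable, and every report
records which grouping produced it.

Because the threshold-averaged probabilities are piecewise constant in ε
(they jump where `⌊ε/ε_th⌋` changes at any quadrature node), the fold
augments the integration grid with every such breakpoint and treats the
probability as exactly constant per segment; yields are then stable under
refinement of the tabulated spectrum grid to well below 0.1 %.

## Thresholds and defaults

| parameter | default | meaning |
|---|---|---|
| p_A, p_B, p_C, p_D | 0.2, 0.2, 0.2, 0.4 | event-type fractions from component molecular weights |
| r₁, r₂, r₃ | 0.13, 0.52, 0.35 | OH-radical fates (0.2·0.65, 0.8·0.65, remainder) |
| ε_th | N(17.5 eV, 5 eV), cut at 7.5 eV | per-event threshold; 9 symmetric quadrature nodes |
| n_bp, window | 73 bp, 10 bp | segment and clustering window |
| j_cap | 60 | event cap (~1 keV); direct ion traversals of a 5 nm site reach several hundred eV, and the lesion spectrum has saturated in DSB(++) well before the cap |

The threshold quadrature places nodes symmetrically over ±4 s.d., weights
them by the normal density, drops nodes under the cut and renormalises —
deterministic, and degenerate (point mass) at zero s.d.  Smearing is an
expectation over ε_th, not per-trial sampling, keeping every reported
quantity deterministic.

Reported tables fold the internally tracked four-break same-strand chain
(SSB(+++)) into the grouped SSB(++) category.  "Total SSB" and "Total BD"
are weighted by the number of breaks or base damages per lesion; single
and double isolated-SSB rows are pattern probabilities; DSB rows are
expected counts, so Total DSB is exactly the sum of its subclasses.

## Degenerate inputs and tie-breaks

Empty segments resolve to the empty state with probability 1; D-only
compositions are inert; zero-window geometry never clusters (only exact
re-hits would, and those collapse); an all-isolated placement that cannot
find room (possible only in pathological geometries) falls back to
bridging placement rather than dropping the break.  Ratio marginals
(DSB : SSB etc.) are NaN at zero multiplicity and excluded from folds with
zero weight.

## Known limitations

* Base damages carry no position within the segment: BD–break co-location
  is resolved only at segment (73 bp) resolution, and the "DSB without BD"
  estimate conditions on no radical BD (or no BD at all) rather than on
  spatial separation.
* Clustering probabilities assume spatially random break placement; real
  track structure (correlated ionizations along δ-ray paths) would modify
  the ladder, and the printed ladder itself cannot be reproduced by plain
  uniform placement — its sampling convention is treated as unknown.
* The per-lesion-uniform attachment rule is an algebraic convention
  validated against the printed expansions, not a geometric derivation;
  the ladder-matched oracle validates the algebra, not the geometry.
* DNA–protein crosslinks, repair, multi-segment (kbp) DSB multiplicity and
  PFGE undercount corrections are out of scope; counting each DSB(++) as a
  single measurable DSB is left to downstream analysis of the reported
  classes.
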