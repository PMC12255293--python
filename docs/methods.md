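# Methods

## The problem and the mechanism

A toehold-mediated strand displacement reaction (SDR) reads out a target
strand by letting it invade a fluorophore/quencher reporter duplex: the
target nucleates at a short single-stranded toehold on the quencher (Q)
strand and displaces the fluorophore (F) strand by branch migration.  Used
as a single-nucleotide-variant (SNV) probe, a plain SDR discriminates poorly:
both alleles react downhill thermodynamically, and the kinetic penalty of a
single mismatch washes out within minutes.

The mismatch-closure design adds a helper strand that base-pairs over the
interrogated position of the *mismatched* target (it is complementary to the
unwanted allele, so on the intended allele the closure carries a mismatch and
sheds).  Closing the site converts the point substitution into a
deletion-like defect: the mismatched target's effective toehold is shortened
by the number of closed bases, its branch-migration domain loses its first
base (which is reassigned to the unpaired spacer), and branch migration can
only begin after the closed junction pair spontaneously opens ("base
breathing").  The intended allele is untouched.  Discrimination therefore
comes from two coupled selections:

* **thermodynamic** — the reaction free-energy gap
  ΔΔG = ΔG_rxn(mismatch) − ΔG_rxn(match) grows from the single-mismatch
  scale (~2 kcal/mol) to the multi-base-pair loss of the closure
  (~5 kcal/mol per closure and rising with closure count);
* **kinetic** — the mismatched pathway is gated by a rare breathing
  excursion, suppressing its apparent rate by orders of magnitude for the
  whole assay, not just its opening minutes.

## Probe-system model

Strands are plain 5'→3' ACGT strings with 0-based half-open domain
annotations.  The matched target is laid out
`[toehold][branch-migration][spacer][association]` with the interrogated base
at the last toehold position; the helper is the reverse complement of the
association domain (its anchor) concatenated with the reverse complement of
the `n_close`-base closure window ending at the interrogated base.  The
reporter Q strand spans `(reverse toehold)* + bm* + toehold*`; F carries the
branch-migration sequence plus any retained reverse toehold (the
toehold-exchange variant).  The spacer is a run of unpaired poly-T bases
whose placement (`bottom`/`helper`/`target`) is a design flag; the default is
the bottom strand.  Which side of the closure carries the anchor is drawn
differently in different realizations of this chemistry; the layout above is
this package's documented convention, and domains are always re-derivable
from the strands by exact complementarity (tested).

## Thermodynamics

Free energies come from the unified DNA nearest-neighbor model: dinucleotide
stack ΔH/ΔS terms plus terminal initiation penalties, with single internal
mismatches handled by the published mismatch stack tables.  The parameters
ship as a plain-text table (`data/nn_params.tsv`, 1 M NaCl / 37 °C
reference, generated from the tables distributed with Biopython and
cross-checked against them in the test suite).  Conditions enter through

* temperature `T` (default 310.15 K — the assay runs at 37 °C);
* an entropic per-stack salt correction `ΔS + 0.368·ln[Na⁺]_eq` with
  `[Na⁺]_eq = [monovalent] + 3.3·√[Mg²⁺]`; the default condition is the 1 M
  NaCl reference at which the shipped ΔG37 column is exact, and
  `ThermoParams.assay_buffer()` gives the TE/Mg hybridization buffer
  (50 mM monovalent equivalent + 12.5 mM Mg²⁺).

A displacement pathway is coarse-grained into ordered states — initial
(zero reference), one state per toehold base pair, an optional breathing
excursion, one state per branch-migration step, incumbent separation — each
computed from the base pairs present in that configuration.  Choices that
matter:

* **Breathing state**: the last toehold state plus the absolute value of the
  two stack terms flanking the first branch-migration pair (the junction
  that must open).  This is always a local maximum because the first
  migration step only forfeits the single junction stack.
* **Migration states in closure mode** are referenced to the
  exchange-neutral profile (each step swaps one incumbent stack for one
  invader stack); the closed gap's full pairing deficit is charged at
  incumbent separation, where the product duplex skips the closure window
  and the junction base.  Configuration sums charge terminal penalties per
  contiguous run, which stands in for the internal-loop penalty of the
  deletion-like product.
* **ΔΔG sign**: `ddG` returns ΔG_rxn(MM) − ΔG_rxn(PM), positive when the
  mismatched reaction is the less favorable one, so that better
  discrimination is a larger positive number and ΔΔG rises with closure
  count.  It is antisymmetric under swapping its arguments.
* Dangling ends, coaxial junction corrections and partition-function
  ensembles are deliberately out of scope: the landscape is the coarse
  pathway cartoon, adequate for state ordering and endpoint free energies,
  not for microstate populations.

## Kinetics

All models are deterministic mass-action ODEs of the overall reaction
A + B → C + D (A target complex, B reporter probe, C product, D released
output, [D] = [C]).

* **One-step** (`simulate_tsdr`): d[C]/dt = k₁[A][B]; the analytic
  equal-concentration solution is the test oracle.
* **Two-step** (`simulate_mcsdr`): A + B ⇌ I (docking/undocking) followed by
  I → C (internal diffusion/alignment, rate `k_align`).  The mismatched
  target inserts a breathing step I → I* with forward rate
  `nu_breathe·exp(−dG_open/RT)` and re-closing rate `nu_breathe`, so the
  step obeys detailed balance; alignment then proceeds from I*.  Every
  intermediate can undock.
* **Multi-closure** (`simulate_multiclosure`): the mismatched target passes
  one breathing step per closed base (a reversible ladder I₀…I_n) before
  alignment; it reduces exactly to the two-step model at one closure.  The
  matched pathway is identical to the two-step matched pathway — the helper
  mismatches it and branch migration over the freed domain is not rate
  limiting, so that stage is absorbed into alignment (`k_bm` is retained in
  the parameter set but unused by the coarse model).

Undocking is thermodynamically coupled to the design:
`k_undock = k_dock · C° · exp(ΔG_toehold/RT)` with C° = 1 M and ΔG_toehold
the nearest-neighbor free energy of the free toehold (full length for the
matched target, shortened by `n_close` for the mismatched one).  The default
opening cost `dG_open` is likewise sequence-derived (the flanking stacks of
the first branch-migration pair, ≈2.3 kcal/mol for the reference design).

Defaults, with rationale:

| parameter | default | why |
|---|---|---|
| `k_dock` | 3×10⁶ M⁻¹s⁻¹ | middle of the 1–6×10⁶ literature range for toehold association |
| `k_align` | 0.02 s⁻¹ | remote-toehold internal diffusion: the toehold is separated from the displacement duplex by the spacer/association geometry, which slows alignment by orders of magnitude relative to a contiguous toehold; this value puts matched apparent rates in the 10³–10⁴ M⁻¹s⁻¹ regime reported for this probe chemistry |
| `nu_breathe` | 10⁴ s⁻¹ | terminal base-pair breathing attempt scale |
| `dG_open` | sequence-derived | opening the closed junction costs its flanking stacks |
| endpoint | 3600 s | the assay's 1 h readout |

With these defaults and the reference design the models give matched/
mismatched apparent rates of ≈7×10³ and ≈6×10¹ M⁻¹s⁻¹ (a ~100-fold gap at
one closure) and a rate gap beyond three orders of magnitude at higher
closure counts — the regime this probe chemistry operates in.

A note on breathing reversibility: making the breathed state decay back at
the attempt frequency is what creates the persistent kinetic gate (the rare
open state almost always re-closes before alignment commits).  An
irreversible breathing step would let every docked mismatched molecule
eventually convert and would erase the discrimination; the reversible ladder
is therefore the model shipped, and the "breathed state dominant" limit
(dG_open → −∞) correctly collapses onto the shortened-toehold matched
pathway.

Mass conservation is exact by construction: only intermediates and product
are integrated; A and B are recovered algebraically.  The integrator is
LSODA at rtol 10⁻⁸ / atol 10⁻¹² on concentrations normalised by the largest
initial concentration.

**Apparent rates** are full-trace least-squares fits of the one-step model
on a 60-point log-spaced grid from 1 s to the endpoint (recorded in trace
metadata; an initial-slope definition would be a different estimator).
`apparent_second_order_rate` uses the closed-form model for speed;
`fitting.fit_rate_constant` is the assay-style procedure — linear signal→
concentration calibration, Nelder–Mead simplex on the rate, sum-of-squared-
residual objective with a fixed 10¹² penalty for negative candidates, ODE
solved inside the objective — and the two routes agree on round trips.

## Design sweep and metrics

`sweep_grid` simulates the 6×5 design grid (toehold 6–11 nt × closures 1–5)
and tabulates endpoint yields, fitted apparent rates,
DF = (F_match − F_blank)/(F_mismatch − F_blank) and DDF = yield²_PM/yield_MM.
Denominators below 10⁻⁶ of the reference scale are flagged (NaN) rather than
extrapolated — with the default parameterization, high closure counts push
mismatched yields below that floor over much of the grid, exactly the regime
where measured DF values become unreliable.  Consequently the
interior-optimum shape of DDF versus toehold length is asserted only on
fully resolvable closure rows; across rows the optimal toehold length
shifts, which is the actionable design statement.

## Synthetic data

The generator emulates a plate reader: signal = intercept + slope·[D] plus
Gaussian noise with an absolute floor (default 0.5 % of the saturation
signal) and a proportional term (default 1 %); one seeded generator per
trace, seed recorded in the metadata, outputs bit-reproducible.  Panels
cover variant-allele-fraction mixtures (matched and mismatched targets
competing for one probe pool through coupled ODEs), target:probe ratio
series, and the 40-fold-excess saturation control that anchors the yield
calibration.  What it does **not** emulate: pipetting/evaporation drift,
photobleaching, secondary structure of long amplicons, enzymatic
pre-processing, or inter-run calibration shifts — so passing tests show the
analysis is correct under the stated noise model, not that it is robust to
every artifact of real instruments.

## Reference design

The bundled design (`reference.py`) is a synthetic stand-in modelled on the
KRAS codon-12 neighbourhood (a G12D-like G→A substitution, probe matched to
the mutant allele): toehold 8 nt, branch migration 20 nt, 2-nt spacer,
16-nt association domain, one closure.  It exists so every sweep, example
and acceptance computation runs on one realistic, fully specified system; it
is not a wet-lab validated probe, and absolute figures (ΔΔG values, apparent
rates, grid maxima) are properties of this design plus the default
parameterization, not universal constants.

## Known limitations

* Coarse state space: no per-step branch-migration random walk, no
  three-way-junction or loop corrections beyond the per-run terminal terms.
* Single-rate fitting only; joint identifiability of (k_dock, k_align,
  nu_breathe) from one trace is out of scope.
* The salt correction is the standard monovalent-equivalent heuristic, not
  an explicit Mg²⁺ binding model.
* Helper binding is treated as saturating on the mismatched target and
  absent on the matched one; partial helper occupancy (relevant for short
  association domains) is not modelled, though the association-domain
  binding energies that would drive such a model are computed.
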