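# Methods

## Model world

Space is a rectangular lattice of `width × height` sites (default
150 × 45 = 6750) with non-cyclic boundaries; +x points distally toward
the migratory target at the max-x edge, +y posteriorly.  One site is
30 µm across, about one neural-crest cell length with extended
protrusions, so one lattice step is a coarse-grained cell movement and a
time step is on the order of hours (the timescale is not calibrated).
Sites carry a three-state machine — Closed (never occupied), Open
(previously occupied), Occupied — with the only legal transitions
Closed→Occupied, Open→Occupied and Occupied→Open.  Open wakes behind
moving agents are the model's "paths of least resistance".

Agents are Leaders or Followers.  Every run starts from a pre-formed
chain: agents single file on the mid-height row at x = 1…n, Followers
rearmost, the default being 3 Leaders + 5 Followers (the stereotypic
few-leaders/many-followers chain).  The tracked ECM variant additionally
opens every site of that row from the front agent to the distal edge.
The analysis deliberately starts *from* the pattern and asks what keeps
it: emergent chain formation from a premigratory population is out of
scope.

## Update scheduling

Each time step performs n agent updates drawn **uniformly with
replacement** (an agent may act twice in a step, or not at all),
mimicking random selection of occupied sites.  This was a genuinely open
reading; we resolved it by behaviour.  Under a strict once-per-agent
shuffle, a fully distally biased chain on an open track locks into a
gap-one single file and every replicate survives to the target (~140
steps of persistence), which contradicts the finite sweep maxima the
model family is known to produce; with-replacement selection makes
inter-agent gaps diffuse and chains break at realistic rates.  The
shuffle scheduler is retained as `scheduler="shuffle"` — it is also the
cleaner setting for several exactness tests (per-step displacement caps,
model-equivalence checks).

## Movement rules

**ECM.**  A selected agent draws a direction from LDD (Leader) or FDD
(Follower); *none* ends the update.  The adjacent site in that
direction: Occupied or out of bounds — the move is cancelled (no pushing
or swapping); Closed — the agent enters only when false is drawn from
POS (the willingness to exert force into intact matrix; one draw per
decision); Open — the agent enters, and when the following site in the
same direction is also Open, a true ATS draw grants a second step
(faster movement along an open channel).  The ATS check re-reads the
site state after arrival.  Diagonal moves need only the destination site.

**Contact.**  Before the per-agent updates, every agent's clocks tick
once (globally, before anyone acts).  Counters decrement with a floor at
the firing point; a counter at zero fires.  A Follower's direction-clock
fire redraws its polarized direction from FDD and resets the clock
uniformly on {0…MDI}; a protrusion-clock fire toggles the protrusion
phase and resets on {0…MPI}.  Protrusions are straight rays of 1–3
sites: a Leader extends up to eight (all directions), a Follower a
single leading-edge ray along its polarized direction.  Extension seeds
1-site rays that grow one site per step to the 3-site maximum;
retraction is instant, except that with probability PPC-true the rays
currently mediating a contact are spared (the toggle phase still flips).
Two agents are in contact when either one's rays cover the other's body
site.  A selected agent in contact moves one site toward the contacted
agent (ties among several contact directions broken uniformly) when true
is drawn from LMC/FMC; a Follower doing so also re-polarizes to the
contact direction, and after a successful contact move a true LRP/FRP
draw retracts all protrusions.  Otherwise Leaders move by a fresh LDD
draw and Followers by their current polarized direction (an unpolarized
Follower stays put).  Closed sites do not impede movement — matrix
resistance belongs to the ECM and Hybrid Models — but occupancy always
blocks.  After any move, each protrusion link that existed beforehand
may adjust its length by ±1 toward the partner's new body site (clamped
to [0, 3]) on a true LMP/FMP draw; on false, or when ±1 cannot restore
coverage, the contact breaks.

**Hybrid.**  Direction choice follows the Contact precedence
(contact move, else LDD/polarized move); execution passes through the
ECM site gate, including POS vetoes (no fallback decision — a vetoed
agent rests) and ATS double-steps, contact-induced moves included.  With
POS-true = 0, ATS-true = 0 and no track the Hybrid reduces exactly, draw
for draw, to the pure Contact Model (a tested invariant): the gate
consumes random numbers only when the corresponding probability is
strictly positive.

### Protrusion readings

Two contact-rule details were genuinely underdetermined and were fixed
by matching the model family's reported default behaviour, then frozen:
gradual (1 site/step) protrusion regrowth rather than instant
full-length extension, and the Follower's single leading-edge ray rather
than a front+rear pair (the "up to two" cap remains in the type
invariants).  Both alternatives remain in version control history only;
the package implements one consistent reading.

## Chain criterion and persistence

Two agents are *sequential* when |Δy| ≤ 1 (no empty site between them
along the anterior–posterior axis) and |Δx| ≤ 4 (at most three empty
sites along the migratory axis).  A **chain** is the longest sequence of
distinct agents, ordered front to back (non-increasing x), whose
consecutive members are sequential; membership is a subset property, so
a straggler cannot destroy a chain formed by the rest.  The longest such
sequence is found exactly by dynamic programming over (member set, last
member) states — with ≤ 8 agents this is 256 × 8 states — and the Python
and compiled implementations share the same tie-break (smallest member
bitmask among equally long chains) so centroids agree bit for bit.  An
earlier greedy ordering was rejected because it broke the definition's
reflection symmetry in y.

The **velocity criterion** requires the chain centroid (mean x of chain
members) to have advanced at least 1 site over the trailing 10-step
window, evaluated at checkpoints t = 10, 20, …; the verdict carries
between checkpoints and is true before the first.  A step counts toward
**persistence** when the structural (≥ 6 members) and velocity verdicts
both hold.  In the default *strict* accounting the run terminates at the
first failure of either criterion — the migratory pattern has broken.
This termination reading was also settled by behaviour: if a failed
velocity checkpoint merely paused the counter, slow "crawl" regimes
(e.g. near-uniform Leader bias walled into the open row by POS-true = 1)
would accumulate hundreds of persistence steps and dominate every sweep,
which is inconsistent with the known finite maxima of this model family.
A *cumulative* mode (`--cumulative`) retains the pause-only reading and
counts non-consecutive chain steps.  Runs also end when any agent
reaches the distal edge (x = width − 1) or at `max_steps` (default 1000;
a grid traversal needs ~150–300 steps, so 1000 is safely terminal).

## Randomness and reproducibility

All simulation randomness flows through one Mersenne Twister stream
seeded per replicate; the numba kernels and NumPy produce identical
streams, and the pure-Python stepping path (`Simulation.step`) is tested
to reproduce the compiled batch kernel's records exactly.  Replicate
seeds derive from a master seed through a counter-based seed sequence
(kept below 2³¹) and are recorded in the output manifest, so any results
file can be regenerated byte for byte.  Because the stream is global,
two interleaved `Simulation` objects share it; replicate-level APIs
(`run_replicates`, the sweeps) always run simulations to completion in
sequence.

## Parameters

| parameter | meaning | default | range |
|---|---|---|---|
| LDD, FDD | Leader/Follower directional distribution | uniform (1/9 each) | 9-value categorical |
| POS | enter Closed ground only on false | 50% true | [0, 1] |
| ATS | double-step through open track | 50% true | [0, 1] |
| LMC, FMC | move toward filopodial contact | 50% true | [0, 1] |
| LRP, FRP | retract protrusions after a contact move | 50% true | [0, 1] |
| LMP, FMP | maintain a stretched/compressed link (±1 site) | 50% true | [0, 1] |
| PPC | spare contact-mediating rays at retraction | 50% true | [0, 1] |
| SID | start Followers polarized distally, shared direction clock | false | flag |
| SIP | shared initial protrusion clock | false | flag |
| MDI, MPI | max direction/protrusion clock interval (steps) | 5 | integer [0, 50] |

Defaults follow the default-baseline convention (distributions uniform,
Boolean distributions 50%, integers 5, flags false).  Without SID,
initial polarized directions are drawn from FDD and clocks independently
from U{0…MDI}; without SIP, protrusion clocks from U{0…MPI}; protrusions
start in the extended phase either way.  Sweep grids: the ECM grid uses
10 directional distal-bias levels evenly spaced from 1/9 to 1 (the
non-distal mass spread equally over the other eight values) × 8 Boolean
levels from 0 to 1, giving the canonical 10·10·8·8 = 6400 sets; the
Contact grid uses the same directional levels, 6 Boolean levels,
MDI/MPI ∈ {0, 5, 10, 20, 35, 50} and both flag values (~4·10⁹
combinations, explored by uniform random sampling).  The exact original
discretizations are not recoverable from the available description;
these grids span the landmark values discussed for this model family
(11%, ~44%, ~60%, ~84%, 100% directional bias) and are overridable.

## Statistics

Each parameter set is summarized by mean persistence ± s.e.m.
(sample SD/√n) over n = 400 replicates (100 for sweep screening, with
the top decile re-run at 400 — screening maxima are selection-biased
upward, so reported maxima always come from the refined replicates).
Pairwise comparisons against a baseline use the Tukey–Kramer method:
the pooled within-group mean square and the studentized-range
distribution (SciPy) give critical half-widths valid for unequal group
sizes at α = 0.05; the implementation is cross-checked against
statsmodels' Tukey HSD.  Sub-group analysis splits sets at mean
persistence ≥ 20, reports per-parameter means ± s.e.m. in both groups
with Welch two-sample p-values (the group variances differ by
construction), value-frequency tables in the high group, and Pearson
product–moment correlations with p-values for r = 0 between all
parameter pairs (SID/SIP coded 0/1).  Degenerate inputs — groups with
fewer than two observations or zero pooled variance — are rejected
rather than silently patched.

## What the simulations do and do not capture

The generator *is* the study system: there are no external data, and
every experiment is a simulation from the initial chain configuration
described above.  The lattice world captures coarse-grained,
hours-per-step collective movement, fixed Leader/Follower phenotypes,
straight ≤ 100 µm filopodia, and a binary forged/unforged matrix.  It
does not capture continuous cell shape or speeds, chemotactic fields
(directional bias is their proxy), contact inhibition of locomotion as a
distinct mechanism, phenotype switching, cell division or death, or
chain assembly de novo.  Passing tests therefore certify the rule
systems and their analysis pipeline, not quantitative agreement with in
vivo trajectories; the published persistence scales used as references
are themselves model outputs, reproduced here within stated tolerances.

Known limitation: the reconstructed Contact rules compress the
persistence scale relative to the original implementation — the default
baseline runs slightly long and the synchronized low-FDD regimes peak in
the high teens rather than above twenty — so the composition of the
high-persistence sub-group is sensitive to the fixed ≥ 20 threshold, and
the sub-group's Leader-bias and SID concentrations come out weaker than
the originally reported ones even though the underlying mechanism
(synchronized initial polarization sustaining chains an order of
magnitude beyond baseline) is present.  The affected checks are reported
as computed, not recalibrated.

## Problem sizes

The test suite and the acceptance script use 400 replicates for baseline
and refined estimates, 100 for sweep screening, the full 6400-set ECM
grid for both track types, and random Contact sweeps of 6000 (tests) or
10,000 (acceptance script) sets; property tests use 10⁴ random
placements against an exhaustive path-enumeration oracle and 10⁵-draw
binomial bounds for the samplers.
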