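# Methods

## The model

netmoa implements a trainable signal-propagation model on a directed
protein-interaction network, of the family used in network-pharmacology
platforms to predict drug mechanisms of action. The biological objects are:

* a **disease characterization**: effector proteins grouped into
  pathophysiological *motives*, each assignment carrying the sign of the
  protein's functional state in disease (+1 hyperactive, -1 hypoactive);
* **drug profiles**: target proteins with an effect sign (-1 for an
  inhibitor), plus *pseudotargets* — proteins not physically bound but
  clamped to represent a blocked interaction (the canonical example is
  clamping MAdCAM-1 to represent blocked integrin–MAdCAM-1 binding);
* **bioflags**: downstream proteins reported in the literature as modulated
  by a drug, used to corroborate model behaviour.

A drug is simulated as a *stimulus*: clamp values in [-1, 1] at its targets
and pseudotargets (effect sign x magnitude, default magnitude 1; a two-drug
combination sums clamp values per protein and clips to [-1, 1]). Signal
propagates over the weighted network by the synchronous update

    a_v  <-  tanh( g * sum_{u->v} w_{u->v} a_u )

for every non-clamped node v, with gain g = 1 so the slope at the origin is
1 and the range is exactly [-1, 1]. Clamped nodes hold their stimulus value
throughout (a `clamp_inputs=False` switch applies the stimulus only as the
initial state instead; it is provided for exploration and carries no
fidelity claim). On acyclic networks the iteration reduces to feed-forward
evaluation. On cyclic networks we use damped iteration
(`damping` default 0.5, tolerance 1e-6, at most 200 iterations); damping
changes the path to a fixed point, not the fixed point itself.
Non-convergence (oscillation at the iteration cap) is never hidden: the
profile carries `converged=False` and downstream analyses surface the flag.
Note that tanh fixed points on cyclic graphs need not be unique (strong
feedback loops admit sign-flipped attractors); the zero-initialized damped
iteration makes the computed profile deterministic and reproducible.

## Training

Edge weights w in [-1, 1] (sign and strength in one parameter) are fit by
simulated annealing against stimulus -> expected-sign rules. An
expectation (protein p, sign s) is *complied with* when the propagated
activity at p has sign s and magnitude >= 0.1 — the same |0.1| threshold
used for reversion calls in the analysis layer, kept identical for
coherence. Accuracy is the complied fraction counted per expectation (the
alternative, per rule, is coarser and was not chosen); an ensemble admits
only solutions with accuracy > 0.90 and is treated as a set of plausible
molecular variants of the same system.

The annealer minimizes a continuous relaxation rather than the discrete
accuracy (which gives no slope to follow):

    L(w) = mean_p max(0, m0 - s_p a_p(w))
         + lambda_sign * sum_{priors violated} |w|
         + lambda_strength * mean_{edges with priors} (|w| - strength)^2

with margin target m0 = 0.3 (comfortably past the 0.1 compliance gate),
soft sign-prior penalty lambda_sign = 0.02, and soft strength-prior penalty
lambda_strength = 1.0. The hinge form matters: expectations already past
the margin stop contributing, so effort concentrates on violated ones.
Priors encode curated evidence about interaction *type* (sign) and
*strength* (magnitude in (0, 1]); both are soft, because curation is
probabilistic, and both may be absent per edge. Strength priors are what
make generalization to held-out rules possible at all: a few dozen rules
cannot identify several hundred edge magnitudes, and without magnitude
information trained models reproduce held-out response *signs* well
(~97% in our benchmarks) while failing the |0.1| magnitude gate on
borderline effects.

Schedule: geometric cooling from T = 0.02 to 5e-6 at rate 0.9, 200
Metropolis steps per level (~16k evaluations). Temperatures are on the
scale of single-move objective changes (~1e-3). A proposal picks one edge
uniformly and either (10%) redraws its weight uniformly — needed to escape
sign-locked configurations — or perturbs it with Gaussian noise whose scale
anneals from 0.5 down to a floor of 0.15x, reflected at the +/-1 bound.
Weights are initialized uniformly at random. Inside the annealing loop all
rules are propagated simultaneously as columns of one activity matrix
(dense below 768 nodes, sparse CSR above), each evaluation warm-starting
from the previous fixed point; the gating accuracy of the returned solution
is always recomputed from a cold start at the user-facing propagation
settings. The stopping rule is the fixed schedule (no adaptive
stabilization criterion); `train_ensemble` retries up to 5x the requested
ensemble size before declaring the gate unreachable, reporting the best
accuracy found.

## Analysis layer

* **fSignal** — the average signal arriving at the effectors. Default
  orientation is *disease-oriented*: mean of (-disease_sign x activity), so
  positive values mean net reversion of the disease state; `raw` mode (the
  literal mean activity) is retained. Within a motive the mean runs over
  (protein, motive) assignments; across the whole characterization it runs
  over unique proteins (a protein in several motives contributes the mean
  of its per-motive oriented values). Reports emit both granularities.
* **Reverted effectors** — sign(activity) opposite the disease sign with
  |activity| >= 0.1, boundary inclusive. Headline percentages count unique
  proteins (motive breakdowns may double-count a protein assigned to
  several motives).
* **Combination decomposition** — for drugs A, B and their combination:
  *convergent* = reverted by A alone and B alone and at least as strongly
  by the combination (|a_AB| >= max(|a_A|, |a_B|) operationalizes "at least
  as strongly"; no stricter formula is defensible from the available
  definitions); *exclusive_A/B* = reverted by one drug alone and maintained
  in the combination; *emergent* = reverted only by the combination;
  *attenuated* = reverted by both drugs alone but more weakly by the
  combination. The five classes partition the relevant proteins; on the
  packaged table fixtures the attenuated and emergent classes are empty.
* **Bioflag corroboration** — per bioflag: *corroborated* if the model's
  activity matches the reported direction with |a| >= 0.1, *antagonised* if
  it opposes at |a| >= 0.1, *below_threshold* otherwise (including exact
  zeros and weak opposition); bioflags absent from the network are reported
  separately and excluded from the evaluated count.
* **Sobol sensitivity** — the stimulus clamp values are perturbed uniformly
  within +/-0.25 of nominal (truncated to [-1, 1]); the output is fSignal.
  First- and total-order indices use the Jansen estimators on the Saltelli
  A/B/AB_i design (N(d+2) evaluations at base sample N, default 1024),
  averaged over ensemble members; the ranking is by total index, ties
  lexicographic. The estimator module is self-contained and validated
  against the analytic additive two-input toy (variance shares
  0.49/0.09 -> indices 0.845/0.155).
* **Mechanism subnetwork** — nodes are the stimulated proteins, reverted
  effectors, and intermediates on directed paths between them carrying
  |ensemble-mean activity| >= 0.1; edges are labelled activation or
  inhibition by the sign of (mean weight x upstream mean activity).
  Exported as DOT (green activation edges, red inhibition, diamond targets,
  filled convergent effectors) and as an edge-list TSV.

## Fixture replay

The packaged fixtures transcribe three published mechanism tables for the
vedolizumab + JAK-inhibitor combination in Crohn's disease: 24
complementary-mechanism rows, 10 convergent effectors, and 22 drug
bioflags. Replaying them maps the printed modulation symbols to symbolic
activities (down -> -0.5, up -> +0.5, none -> 0; corroboration statuses
analogously, with below-threshold cases at 0.05) — a fixture convention,
not a model claim, since every classification depends only on signs and the
0.1 threshold. The pipeline's own classification then reproduces the
published tallies exactly: 13 drug-A-exclusive reversions (6 in motive 1),
11 drug-B-exclusive (7 in motive 4), 10 convergent effectors, and 20
corroborated bioflags under the combination. One transcription note: the
convergent table's body and the accompanying text disagree on one gene
symbol (MAPK3 vs "PAMK3"); the fixture records MAPK3 and flags the
discrepancy rather than silently resolving it. Similarly, the source
reports one motive with 59 effectors in one place and "50" in another;
the fixtures document both without reconciling them.

## Synthetic benchmark systems

The curated network and training corpus this kind of platform runs on are
proprietary, so the package generates its own benchmark systems with the
statistical structure the analysis assumes:

* **Topology** — scale-free (preferential attachment, 70% of edges oriented
  away from the older node), small-world (rewired ring with random edge
  orientation), or random DAG; ~3 edges per node by default.
* **Motives** — sizes 50/24/45/59 at full scale, overlapping to 148 unique
  effectors (overlap fraction 30/178); membership is allocated
  constructively (each pool member gets one motive with probability
  proportional to remaining capacity, then motives fill remaining capacity
  with duplicates), which hits the requested unique total exactly without a
  rejection loop. A designated motive can be *detached*: its effectors
  receive members outside the drug-reachable region and every in-edge from
  that region is severed, making structural reachability zero — the
  situation in which an analyst would exclude a motive from modelling.
* **Ground truth and priors** — planted weights uniform in [-1, 1]; sign
  priors record the planted sign exactly, strength priors the planted
  magnitude blurred with N(0, 0.1) observation noise (clipped to
  [0.05, 1]), emulating curated evidence of interaction type and strength.
* **Rules** — drug stimuli plus random 1–3-protein stimuli are propagated
  through the ground truth; expected signs are recorded for effectors with
  |activity| >= 0.1, at most 5 per rule, so the rule set stays smaller than
  the number of free weights (the under-determination that makes an
  ensemble of distinct valid solutions meaningful). At zero rule noise the
  planted solution scores accuracy 1.0 by construction; `rule_noise` flips
  that fraction of expected signs.
* **Planted synergy** — dedicated target nodes wire to three disjoint
  effector blocks: exclusive-to-A, exclusive-to-B (one drug each), and
  convergent (one edge from each drug, same-signed weights, so the combined
  clamp strictly strengthens the response). Planted effectors are leaves
  with no other in-edges, and filler effectors are drawn outside the
  drug-reachable region, so the decomposition computed on the ground truth
  recovers the planted sets exactly and the combination's reversion
  percentage dominates each monotherapy's in every seed.

The desk-scale configuration used for routine runs is 120 nodes, motive
sizes 12/6/10/14, 2 drugs x 3 targets, 25 rules. Its default topology is
the random DAG: feed-forward propagation has a unique fixed point, which
makes training-recovery measurements well-posed (cyclic tanh networks can
be bistable, in which case the "recovered" profile depends on the
iteration history); cyclic topologies are exercised by the propagation
oracle and property tests. Problem sizes throughout the test suite and the
acceptance script (120-node systems, 20-30 rules, ensembles of 5, 100
small-network oracle comparisons, 1024 Saltelli base samples) were chosen
to characterize behaviour at workstation scale.

What the synthetic systems do **not** emulate: the topology statistics of
real curated interactomes beyond the named generator families; cell-type
specificity (profiles are multicellular averages, as in the source
platform); literature curation noise other than i.i.d. sign flips; and the
scale of real training corpora. Passing the recovery benchmarks shows the
optimizer and analytics are correct and well-conditioned under these
planted conditions — not that the approach recovers mechanisms from real,
noisy, incompletely curated biology.

## Numerical and design choices

* Reversion boundary is inclusive (|a| >= 0.1 counts).
* Weight bound w_max = 1; proposals reflect at the bound.
* Propagation is bitwise deterministic given (network, solution, stimulus,
  config); the full pipeline report is byte-identical across reruns with
  the same config and seeds (timestamps are excluded from the report).
* Sorting conventions: nodes and edges lexicographic; ensemble members by
  accuracy descending then seed; Sobol ranking by total index descending
  then name.
* Degenerate inputs fail loudly with named offenders: empty target sets,
  duplicate (protein, motive) assignments, stimulated proteins absent from
  the network, non-finite weights, non-positive tolerances, fewer than two
  Sobol parameters.

## Known limitations

* The annealing schedule is fixed; no adaptive stopping or reheating.
* Warm-started inner evaluations on *cyclic* networks may track one of
  several fixed points during training; the reported accuracy is always
  re-evaluated from a cold start, but the optimizer's search signal can be
  noisier there than on DAGs.
* Held-out-rule compliance depends on the margin structure of the planted
  system: expectations whose ground-truth magnitude sits barely above the
  0.1 threshold are intrinsically brittle under any weight redraw
  consistent with the priors.
* The combination rule (sum then clip) and the clamp semantics of stimuli
  are modelling choices; the platform this emulates does not document its
  exact conventions.
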