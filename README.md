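# graspaff

**Integrated learning of grasp affordances and reach-to-grasp motor
parameters in a simulated parieto-premotor system.**

`graspaff` is a neural simulator for computational neuroscientists studying
how an embodied agent can *simultaneously* learn what object features
afford a grasp and which motor parameters realize it, from nothing but
trial-and-error reinforcement. A kinematic 22-degree-of-freedom arm/hand
reaches for primitive objects (cubes, prisms, cylinders, spheres, plates);
model parietal areas encode each object's direction, distance, axis
orientation, visible surface normals and size as Gaussian population
codes; a reward-modulated self-organizing map — the model anterior
intraparietal area (AIP) — compresses them into an affordance
representation; and dynamic neural fields in model premotor areas (F2, F5,
F7, F2/F5) select the reach target, reach offset, grasp type, maximum
aperture and wrist rotation by winner-take-all competition.

The three learning rules at the core:

* **Affordance map.** A 40×40 toroidal self-organizing map over the
  normalized parietal vector **I**, with activity `AIP(i,j) = W(i,j)·I + ε`
  and competitive updates `W ← W + Θ(β;r)·α·(I − W)`, where the
  neighborhood `Θ = exp(−β²/2r²)` (truncated at r, toroidal index distance
  β) and both `r(T) = r₀e^(−T/λ) + rs` and `α(T) = α₀e^(−T/λ) + rs` are
  *expanded by the reinforcement signal rs* — rewarded inputs recruit more
  of the map.
* **Winner-take-all fields.** Leaky-integrator grids
  `τu̇ = −u + h + IN + f∗W + ε`, `f = σ(β(u−u₀))`, with a
  center-excitation/global-inhibition kernel; execution populations are
  released by a go signal (tonic inhibition GP: 10 → 0).
* **Reward-modulated Hebbian learning.** Every learned projection updates
  as `ΔW = α·rs·pre⊗exec`, using execution-field firing as the eligibility
  trace: Hebbian after a stable grasp, anti-Hebbian after a failure.

A grasp counts as stable when two contacts from opposing hand parts define
an opposition axis passing through the object, held for 2 s — the only
physics the learning loop consumes, supplied here by a geometric contact
surrogate instead of a rigid-body engine (see `docs/methods.md`).

## Worked example

Pretrain the affordance map and measure how shape-selective its units
become (the preference index PI of a unit over the five object shapes is
`(n − Σrᵢ/r_pref)/(n − 1)`; 1 = responds to one shape only):

```python
from graspaff import GraspModel, ModelConfig
from graspaff.analysis import selectivity_timecourse

model = GraspModel(ModelConfig(seed=1))
records = model.pretrain_aip()            # 1000 trials, no movements
for rep in selectivity_timecourse(records, block=500):
    print(rep.block, rep.counts, round(rep.mean_pi, 2))
```

```
0 {'high': 0, 'moderate': 1537, 'non': 63, 'excluded': 0} 0.42
1 {'high': 1287, 'moderate': 313, 'non': 0, 'excluded': 0} 0.84
```

Every one of the 1600 map units starts out moderately shape-selective
(random weights respond to everything); by the end of pretraining ~80 %
of units are highly shape-selective (PI > 0.75) even though shape is never
explicitly encoded — the map discovers it from the co-occurrence of size,
orientation and surface features.

The full curriculum — map pretraining, wrist-rotation pretraining
(palm-contact reward), then grasp training with a mid-training
novel-object probe — runs from the command line; `--scale N` divides the
stage lengths and coarsens the control step for desk-scale runs:

```bash
graspaff train --seed 1 --scale 10 --checkpoint model.h5 --out trials.h5
graspaff analyze --log trials.h5 --out reports/
```

## Package layout

| module | contents |
|--------|----------|
| `graspaff.kinematics` | 22-DOF arm/hand, closed-form FK, analytic Jacobian, pseudo-inverse IK, PD control |
| `graspaff.objects` | object primitives, signed distances, spherical pose |
| `graspaff.contacts` | contact detection, opposition-axis stability, collision surrogate |
| `graspaff.populations` | parietal population codes and the map input vector |
| `graspaff.som` | the reward-modulated self-organizing affordance map |
| `graspaff.dnf` | dynamic neural fields (1/2/3-D winner-take-all) |
| `graspaff.premotor` | F2/F5/F7/wrist fields, fixed relays, reinforcement updates |
| `graspaff.dmp` | dynamic movement primitives |
| `graspaff.motor` | decoding, grasp plans, reach/grasp-phase controllers |
| `graspaff.training` | trial protocol, staged curriculum, object sampling |
| `graspaff.analysis` | preference index, selectivity time courses, success curves, linear feature fits |
| `graspaff.io` / `graspaff.cli` | checkpoints, trial logs, command line |

`docs/methods.md` documents the model equations, parameter choices and
limitations in detail.
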