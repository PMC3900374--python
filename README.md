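# walkleader

Leader–follower network inference from high-frequency GPS tracks of group
walks.

When several animals move together — here a dog group walking off-leash
with its owner — "who leads whom" is written into the fine structure of
their trajectories: a follower copies the leader's direction changes with a
short time delay. `walkleader` implements the full analysis chain from raw
5 Hz GPS fixes to a leadership hierarchy, together with an agent-based walk
simulator that provides ground-truth couplings for testing, and the
small-sample statistics used to relate movement-derived metrics to
per-individual trait scores.

## The method

For a pair of moving individuals *i, j* with unit heading vectors
**u**<sub>i</sub>(t), the time-windowed directional correlation is

> C<sub>ij</sub>(t, τ) = ⟨ **u**<sub>i</sub>(s) · **u**<sub>j</sub>(s + τ) ⟩<sub>s ∈ window(t)</sub>

evaluated over a 6 s window and a ±5 s lag grid. When the maximum over τ
exceeds C<sub>min</sub> = 0.95 (an 18.2° mean heading difference), the
maximising delay τ* is an interaction event; τ* > 0 means *i*'s direction
changes precede *j*'s. Events pooled over walks form a per-pair delay
histogram; its Gaussian-smoothed (σ = 0.3 s) mode, bootstrap peak
stability, and a randomization null built from 4000 composite histograms
decide whether the pair is unconnected, evenly matched, or directed, and a
Gaussian fit around the peak gives the fraction of interactions led by the
leader. Directed edges assemble into a network on which each individual's
*leading tendency* (number of individuals reachable along directed edges)
is the leadership rank. An independent vicinity network (time within 5 m
of each other vs a circular time-shift null) cross-checks the edges without
requiring synchronised movement.

Because raw data of this kind are rarely deposited, the package ships a
generator (`walkleader.synthetic_walks`) that emulates the study design —
an owner walking a smooth path at ~1.1 m/s, dogs running out-and-back loops
at individual preferred speeds, episodic joint loops with pair-specific
heading-copy delays, 5 Hz sampling, 1.5 m GPS noise — and records every
imposed coupling as ground truth.

## Worked example

```python
import walkleader as wl

cfg = wl.SimConfig(
    n_dogs=4, duration=600.0,
    coupling={(1, 2): wl.Coupling(0.4),   # D1 leads D2 by 0.4 s
              (1, 3): wl.Coupling(0.8),   # D1 leads D3 by 0.8 s
              (2, 3): wl.Coupling(0.4)})  # D2 leads D3 by 0.4 s
walks, truth = wl.generate_study(cfg, n_walks=14, seed=1)
result = wl.analyze_study(walks, wl.DelayConfig(), seed=1)
for r in result.relations:
    print(r.pair, r.status, r.leader, round(r.tau_mode, 2),
          None if r.status != "directed" else round(r.leading_ratio, 2))
print(result.node_table())
```

prints

```
('D1', 'D2') directed D1 0.4 0.67
('D1', 'D3') directed D1 0.8 0.93
('D1', 'D4') unconnected None -3.95 None
('D2', 'D3') directed D2 0.35 0.65
('D2', 'D4') unconnected None 0.1 None
('D3', 'D4') unconnected None 4.05 None
      leading_tendency  active_connections
node
D1                   2                   2
D2                   1                   2
D3                   0                   2
D4                   0                   0
```

All three imposed couplings are recovered as directed edges with delay
modes within 0.05 s of the truth, the uncoupled dog D4 stays isolated, and
the leading ratios reflect the simulated 70 % episode-level role share.
The delay mode is the peak of a wide distribution — leader and follower
roles swap dynamically — which is why the bootstrap-stability test, not
the mode alone, decides connectivity.

A command-line interface mirrors the library
(`walkleader simulate | preprocess | metrics | delays | network | correlate`);
run any subcommand with `--help`.

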