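# hawkdove

Agent-based hawk-dove game dynamics in group-structured populations.

Agents live in groups and play pairwise hawk-dove contests with random
group-mates for resources. An agent reproduces whenever its resources
reach a threshold `T`, paying `T` per attempt; births succeed only
while the population is below a hard cap `N_max` (a Moran-like
process). Offspring inherit the parental pure strategy with a small
mutation rate `m_r`, and either stay in the natal group or disperse to
a random other group with probability `d`. Lifespans are Gaussian
draws; mortality is lifespan-only. Groups fission into two random
halves on reaching `GS_max` members and fuse into a random other group
at `GS_min` members or fewer.

The headline phenomenon: with costs above benefits the classic
analysis predicts a stable hawk frequency of `b/c`, and well-mixed
simulations reproduce it — but small maximum group sizes drive the
evolved hawk frequency far below `b/c` (about 10–12% hawks at
`GS_max=12` with `b/c = 0.5`), and increasing natal dispersal
dissolves the effect (with an overshoot above `b/c` for small groups
at high dispersal).

## Library quick start

```python
import hawkdove as hd

cfg = hd.SimulationConfig(structured=True, b=6, c=12, GS_max=12,
                          N_0=600, N_max=2500, n_steps=50_000, seed=1)
series = hd.run(cfg)
print(hd.equilibrium_hawk_frequency(series))   # ~0.115 << b/c = 0.5
```

Modules:

- `hawkdove.game` — payoff matrix, analytic ESS `min(1, b/c)`,
  expected-payoff oracles.
- `hawkdove.population` — array-backed `Population` with `Agent` /
  `Group` proxies; lifespan draws, reproduction with the Moran-like
  cap, natal dispersal, group fission/fusion.
- `hawkdove.engine` — the per-step scheduler (games → reproduction →
  aging/mortality → group maintenance) and `run()`.
- `hawkdove.experiments` — the three studies (validation cost sweep,
  group-size sweep, dispersal sweep) plus equilibrium summaries.
- `hawkdove.config` / `hawkdove.cli` — flat TOML configs and the CLI.

## CLI

```bash
# one trajectory -> CSV + TOML + JSON manifest
hawkdove run --set c=12 --set GS_max=12 --seed 1 --steps 50000 --out-dir out/

# sweeps at desk scale (N_0=600, N_max=2500, 5e4 steps);
# --full restores the published scale (N_0=2400, N_max=10000, 1e7 steps)
hawkdove sweep validation --replicates 5 --seed 7 --out-dir out/
hawkdove sweep group-size --replicates 5 --seed 7 --out-dir out/
hawkdove sweep dispersal  --replicates 5 --seed 7 --out-dir out/

# post-burn-in mean hawk frequency of a saved time series
hawkdove summarize out/run_timeseries.csv --burn-in 0.5
```

## Reproducibility

Every run is fully determined by its `SimulationConfig` (including
`seed`); sweep replicates draw independent seeds from the root seed
via `numpy.random.SeedSequence`. Rerunning any config bit-identically
reproduces its time series.

One modelling ambiguity is exposed as a flag: `fuse_at_or_below`
(default `True`) fuses groups at exactly `GS_min` members as well as
below; the default reproduces the published suppression levels, the
strict `< GS_min` trigger equilibrates a few points lower.
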