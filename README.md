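# talin-clutch

Mechanochemical modelling and single-molecule kinetic analysis of the
Talin **elastic transient clutch** — the brief, stretchable linkage by
which Talin couples the rearward-flowing lamellipodial actin network
to immobile integrin adhesions and transmits force to the substrate.

The package is for quantitative cell biologists and biophysicists who
want to (a) simulate how force-dependent unfolding of Talin's rod
subdomains shapes the lifetime of, and work done by, a single clutch
linkage, and (b) analyse single-molecule-speckle (SiMS) trajectories
of adhesion proteins — classification, nanometer flow-onset jumps,
censored survival rates, state proportions — with a synthetic-data
generator that closes the loop.

## The model

A Talin molecule is a chain of N rod subdomains plus two end linkers,
anchored to a fixed integrin and to actin moving at the retrograde
flow speed v.  Folded subdomains are Hookean springs,
F = k_f(l − l_f0); unfolded subdomains are freely jointed chains,
F = (kT/b)·L⁻¹(l/(b·n)).  Subdomain unfolding and integrin unbinding
follow Bell's law, k(F) = k₀·exp(F·Δx/kT) (a catch–slip integrin bond
is available as a variant).  The linkage state — which subdomains are
unfolded, bound or unbound — evolves either by a discrete-time master
equation under uniform tension, or by explicit overdamped bead–spring
simulations with Monte Carlo events; the two methods cross-validate.

On the experimental side, the four-state kinetic scheme
stationary ⇄ clutch ⇄ flowing (+ diffusing) is estimated from speckle
tracks via Kaplan–Meier survival analysis with photobleaching
correction, and the steady-state flux balance

    dS/dt = −k_a·S + k_b·C + X = 0
    dC/dt =  k_a·S + k_d·F − (k_b+k_c)·C = 0
    dF/dt =  k_c·C − k_d·F − X = 0,   X = k₂·S − k₄·F

yields the proportions of stationary (S), clutch-engaged (C) and
flowing (F) molecules.

## Worked example

```python
from talin_clutch import TalinChainModel, ChainConfig, clutch_flux_balance

# a 12-subdomain Talin at 45 degrees to the substrate, 20 nm/s flow
model = TalinChainModel(ChainConfig(n_total=12, n_unfoldable=12,
                                    theta0=45.0, v_retro=20.0))
print(model.solve().summary())
print()
ens = model.simulate(n=200, seed=7)
print(ens.summary())
print()
sol = clutch_flux_balance(57.0, {"k_a": 0.0548, "k_b": 0.374,
                                 "k_c": 0.680, "k_d": 0.0315,
                                 "k_2": 0.0324, "k_4": 0.00694})
print(f"clutch-state proportion C = {sol.C:.2f}%  (F = {sol.F:.1f}%)")
```

prints

```
Talin clutch master-equation run
  N = 12, M = 12, theta0 = 45.0 deg, v_retro = 20.0 nm/s
  path: homogeneous, dt = 0.001 s, steps = 20000
  P_unbound(end)        = 1.000000
  mean clutch duration  = 2.5333 s
  mean work on actin    = 309.114 pN nm
  mean unbind displacement = 50.67 nm

Talin pulling ensemble
  N = 12, M = 12, theta0 = 45.0 deg, v_retro = 20.0 nm/s
  n = 200, dt = 1e-06 s, zeta = 0.0001 pN s/nm, seed = 7
  mean unbinding time = 2.520 +- 0.140 s
  mean work on actin  = 305.0 +- 21.1 pN nm
  mean unfold events  = 3.52
  censored traces     = 0

clutch-state proportion C = 4.15%  (F = 39.7%)
```

The master equation says a fully unfoldable 12-subdomain chain stays
engaged for ~2.5 s on average and does ~310 pN·nm of work on the actin
network per linkage (roughly double the ~1.3 s / ~213 pN·nm of a chain
that cannot unfold — unfolding is what makes the clutch effective);
the stochastic ensemble agrees within its standard error.  The flux
balance of the measured rate constants puts ~4% of speckle-visible
Talin in the mechanically engaged clutch state at any instant.

On the analysis side:

```python
from talin_clutch import SpeckleKinetics, KineticGroundTruth, ImagingModel, generate_tracks

tracks, truth_labels = generate_tracks(KineticGroundTruth(),
                                       ImagingModel.coarse(), 1000, seed=0)
fit = SpeckleKinetics(tracks, mode="coarse_2s", window=120.0).fit()
print(fit.summary())
```

recovers the generating rate constants (k₁ ≈ 0.17, k₂ ≈ 0.03,
k₃ ≈ 0.10, k₄ ≈ 0.01 s⁻¹) from noisy, bleaching, censored tracks.

A command-line interface mirrors the library:

```bash
talin-clutch simulate-me --config cfg.yaml --out me.json
talin-clutch simulate-pulling --config cfg.yaml -n 1000 --seed 7 --out ens.json
talin-clutch sweep --vary n_unfoldable=0..12 --out sweep.json
talin-clutch synth-tracks -n 1000 --seed 3 --out tracks.csv --labels labels.csv
talin-clutch analyze-tracks tracks.csv --out rates.json
talin-clutch flux-balance --s 57
talin-clutch bookkeeping
```

Every run writes a versioned JSON embedding the resolved configuration
and seed, so results are reproducible from the output file alone.

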