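# jcelottery

Spatially explicit lottery models and mean-field ODE approximations of
**Janzen–Connell effects (JCEs)** — the elevated mortality of tree seeds and
seedlings near conspecific adults caused by specialised natural enemies —
under four functional forms of specialised predation. The package is for
theoretical community ecologists who want to ask: *when can JCEs prevent
competitive exclusion in a community with interspecific fitness variation,
and how much does the assumed shape of predation pressure matter?*

## The models

A community of `N` species occupies a gridded torus of `M` patches, one
adult per patch. Each time-step adults die with probability `δ` and are
replaced by a lottery over the offspring on their patch. Offspring
abundances on a patch occupied by species `k` at location `x` are

```
S_ii(x) = Y_i (1 − D + p_i D) J_ii(x)        (natal patch)
S_ik(x) = Y_i p_i D J_ik(x)                  (k ≠ i)
```

with `Y_i` intrinsic fitness (lognormal across species, `ln Y ~ N(0, σ_Y²)`),
`p_i` the global adult proportion, `D` the community-wide dispersed seed
fraction, and `J` the JCE survival kernel. Predation varies on two axes —
additive vs non-additive in conspecific adult density, fixed-radius vs
exponential distance decay — giving four forms:

| form | survival on a heterospecific patch |
|------|-------------------------------------|
| NF   | `e^(−a)` if a conspecific adult is within `r`, else 1 |
| AF   | `exp(−a · #{conspecific adults within r})` |
| ND   | `exp(−a e^(−d_min/v))`, `d_min` distance to nearest conspecific |
| AD   | `exp(−a Σ_m e^(−d_m/v))`, summed over all conspecific adults |

Taking expectations over the adult configuration yields per-form closed
forms for `E[S]` (`E_F = πgr²`, `E_D = 2πgv²`, and for AD the generalised
hypergeometric `H(a) = ₃F₃(1,1,1;2,2,2;−a)`), and deterministic community
dynamics

```
dp_i/dt = δ [ (E[S_ii]/E[S_all,i]) p_i + Σ_{k≠i} (E[S_ik]/E[S_all,k]) p_k − p_i ].
```

The package also implements the inter-model normalisations (equal per-tree
total predation pressure ⇒ `r = v√2`; equal mean predation ⇒
`a_n = a_A (1 + E/N_A)`), approximate invasion criteria with their
mean-JCE-fitness / covariance-JCE decomposition plus an exact bisection
oracle, and drivers for richness sweeps, survival curves and paired
spatial/ODE validation. Default parameters are anchored to the Barro
Colorado Island 50-ha plot (`g ≈ 0.172` adults·m⁻², extinction below
`ln p < −11`).

## Worked example

```python
import math
from jcelottery import JCEForm, sample_fitness, normalized_parameter_set, run_ode

aA = -math.log(1 - 0.4)          # baseline predation: 40% death near conspecifics
Y = sample_fitness(300, sigma_Y=0.55, seed=1)
nps = normalized_parameter_set(aA, v=10.0, g=0.172, D=0.5, sigma_Y=0.55,
                               seed=1, N0=300, Y=Y)
for form in JCEForm:
    res = run_ode(Y, nps[form], D=0.5)       # 10,000 generations
    print(form.name, res.richness)
```

prints

```
NF 7
AF 124
ND 6
AD 143
```

Starting from 300 species with moderate predation (`1 − e^(−a_A) = 0.4`) and
substantial fitness variation, the additive models preserve two orders of
magnitude more species than the non-additive ones, and additive-distance-decay
(AD) — the form closest to empirical measurements — preserves the most. At
very strong predation (`0.99`) the same pipeline prints `NF 211, AF 211,
ND 279, AD 294`: every form now maintains high richness, and the
distance-decay forms lead.

The command-line interface exposes the same drivers
(`jcelottery sweep|validate|survival-curves|invasion|normalise`); each run
writes tidy CSVs plus a JSON summary and a manifest.

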