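# isletins

**Kinetic model of the monomeric-insulin microenvironment of a single
pancreatic islet.**

Insulin acts back on the β-cells that secrete it, but the concentration of
*receptor-active monomeric* insulin inside an islet of Langerhans cannot be
measured directly. Insulin is secreted as zinc-stabilised hexamer crystals
that must dissolve into dimers and then monomers before they can bind the
insulin receptor, and most of what a β-cell sees may in fact be monomeric
insulin *returning* from the peripheral circulation. This package implements
a four-state kinetic model that estimates both contributions as a function of
clamped glucose, for anyone studying autocrine/paracrine insulin signalling,
islet physiology, or β-cell dose-response experiments who needs a defensible
estimate of the intra-islet insulin concentration.

## The model

State variables (pM): hexamers $h$, dimers $d$, newly produced local
monomers $m$, and returned peripheral monomers $I_p$.

$$
\begin{aligned}
\dot h &= s(G)/6 - p\,(h - q d^3) \\
\dot d &= 3p\,(h - q d^3) - \hat p\,(d - \hat q m^2) \\
\dot m &= 2\hat p\,(d - \hat q m^2) - (c + d_i)\, m \\
\dot I_p &= k m - d_i I_p
\end{aligned}
$$

Secretion enters as hexamers (hence $s(G)/6$), each hexamer yields three
dimers and each dimer two monomers; $p, \hat p$ are dissolution rates with
mass-action re-aggregation corrections $q, \hat q$; local monomer is cleared
by transfer to the circulation ($c$) and degradation ($d_i$); the returned
peripheral pool is fed in proportion to local monomer ($k$) and degrades at
the same $d_i$. Glucose-stimulated secretion is a Hill function
$s(G) = \sigma G^\gamma/(\alpha^\gamma + G^\gamma)$ fitted by least squares
to published in-vivo human secretion rates.

The system is cooperative and has a unique, globally asymptotically stable
equilibrium with the closed form

$$
m^* = \frac{s(G)}{c + d_i},\quad
I_p^* = \frac{k}{d_i} m^*,\quad
d^* = \frac{s(G)}{2\hat p} + \hat q\, m^{*2},\quad
h^* = \frac{s(G)}{6p} + q\, d^{*3},
$$

so the new-to-returned monomer ratio $m^*/I_p^* = d_i/k$ is independent of
glucose. With the default calibration ($d_i = \ln 2 / 6\ \mathrm{min}^{-1}$
from the 6-min insulin half-life, $k = 3 d_i$ from the 75% peripheral share,
$c + d_i = 0.5\ \mathrm{min}^{-1}$), 75% of intra-islet monomeric insulin is
returned peripheral insulin and the total stays in the 50–300 pM range over
physiological glucose.

## Worked example

```python
>>> import isletins as ii
>>> params = ii.default_params()          # fits the Hill curve, calibrates rates
>>> params.hill
HillParams(sigma=111.96009664990699, alpha=9.404688066876394, gamma=3.14688558465387)
>>> eq = ii.equilibrium(params, 7.0)      # clamped glucose 7 mM
>>> round(eq.m, 1), round(eq.ip, 1), round(eq.total_monomer, 1)
(63.4, 190.2, 253.5)
```

At a 7 mM glucose clamp (upper end of a normal meal excursion) the model
predicts 63.4 pM of newly secreted monomer and 190.2 pM of returned
peripheral monomer — 253.5 pM total, with exactly 75% of it peripheral.
The same numbers from the command line, plus the transient after a step
from 0 to 10 mM glucose:

```console
$ isletins equilibrium -g 7
glucose_mM,h_pM,d_pM,m_pM,Ip_pM,total_monomer_pM,new_fraction,peripheral_fraction
7.0,10.56429141404874,15.84683889637478,63.38574848425476,190.1572454527643,253.54299393701905,0.25,0.7500000000000001

$ isletins -v step -g 10 --t-end 120 > /dev/null
INFO within 10% of Ip* at t=25.54 min
```

Returned peripheral insulin comes within 10% of its equilibrium about 25.5
minutes after the step — the "reaches its maximum in ~30 minutes" behaviour.
Other subcommands: `fit`, `sweep`, `validate`, `synth`, `params` (run
`isletins --help`); a TOML `--config` overrides the physiological anchors.

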