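# cmbdf

Convolutional many-body distribution functional (cMBDF) representations:
compact, fixed-length atomic environment descriptors for machine learning
of molecular properties, with analytic nuclear gradients.

## The problem

Kernel and tree-based ML models for chemistry need a numeric encoding of
each atom's surroundings that is invariant to translation, rotation and
atom relabeling, and whose length does not grow with the number of
chemical elements or neighbors.  Most established descriptors (SOAP, ACSF,
FCHL-type) trade accuracy against vectors of hundreds to thousands of
components.  cMBDF encodes an environment in tens of components by taking
*functionals* of smooth many-body distributions instead of binning them.

## The method

A smooth density is placed around each atom *i*,

```
rho_i(r) = sum_j A(Z_j) N(r; R_ij, sigma),        N = normal PDF,
```

projected onto internal coordinates: interatomic distances (two-body),
angles with Axilrod–Teller–Muto damping `(R_ij R_ik R_jk)^-2` (three-body),
and an effective quadruplet coordinate obtained by the Gaussian product
theorem (pseudo four-body).  Feature components are integrals of weighting
functions `g_n` against derivatives of these distributions,

```
P_nu,n,m[i] = ∫ g_n(x) d^m/dx^m rho_i(x) dx .
```

Because each derivative of a Gaussian is a Hermite–Gaussian `f_m`, every
component collapses to a weighted sum of values of the convolution
`H_nu,n,m = g_n * f_m` — a system-independent 1-D function computed once by
FFT, stored on a grid, and only ever *looked up* thereafter.  With
many-body order ν, derivative orders m = 0..m_max and weighting orders
n = 0..n_max−1 over two function families per body order, the per-atom
vector has fixed length

```
2 (nu - 1) (m_max + 1) n_max        # 40 for (3, 4, 2), 60 for (4, 4, 2)
```

independent of composition, neighbor count and cutoff.  Gradients come
almost free: differentiating a lookup raises the Hermite degree by one,
`dH_m/dx = -(1/(sqrt(2) sigma)) H_{m+1}`, so analytic nuclear gradients
reuse the same grid set.

The package also provides a direct-quadrature oracle (the integrals the
convolution trick replaces), a deterministic synthetic-molecule generator
with toy Morse-energy labels, a minimal kernel-ridge-regression harness,
and a CLI (`cmbdf featurize|grids|fixtures|learn|selftest`).

## Worked example

```python
import numpy as np
from cmbdf import CmbdfConfig, Molecule, atomic_representation, representation_gradients

cfg = CmbdfConfig()            # nu=3, m_max=4, n_max=2 -> 40 features
grids = cfg.build_grids()
water = Molecule(Zs=[8, 1, 1],
                 coords=[[0.0, 0.0, 0.0], [0.9572, 0.0, 0.0], [-0.2400, 0.9266, 0.0]])
vec = atomic_representation(water, 0, cfg, grids)
print('feature length:', vec.shape[0])
print('first pair-block components:', np.round(vec[:4], 4))
grad = representation_gradients(water, cfg, grids)
print('gradient tensor shape:', grad.shape)
print('translation null-space residual:', float(np.abs(grad.sum(axis=2)).max()))
```

prints

```
feature length: 40
first pair-block components: [ 0.3741  0.303  -0.232  -1.4562]
gradient tensor shape: (3, 40, 3, 3)
translation null-space residual: 1.7053025658242404e-13
```

The 40 components are the oxygen atom's invariant fingerprint (blocks
ordered by body order, weighting type, n, m); the gradient tensor holds
the derivative of every component of every atom with respect to every
nuclear Cartesian coordinate, and its exact zero row-sum reflects
translation invariance.

Learning on the built-in synthetic Morse task (median test MAE in toy
energy units over two seeds):

```python
from cmbdf import toy_learning_curve
recs = toy_learning_curve(train_sizes=(100, 400), n_test=150, seeds=(0, 1))
```

```
N= 100  median test MAE = 12.584
N= 400  median test MAE = 8.398
```

— the error falls with training-set size, as a working representation must
make it do.

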