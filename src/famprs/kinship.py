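"""Pedigree kinship coefficients and the additive relationship matrix.

Kinship phi_ij is the probability that one allele drawn at random from i and
one from j are identical by descent. It is computed by the recursive tabular
method: processing individuals parents-first,

    phi_ij = (phi_{f j} + phi_{m j}) / 2     for i with parents (f, m), j != i
    phi_ii = (1 + phi_{f m}) / 2
    founders: phi_ii = 1/2, phi between distinct founders = 0.

The mixed models use 2*phi (the additive/numerator relationship matrix) as
the covariance structure of the polygenic random effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Pedigree, PedigreeError


@dataclass(frozen=True)
class KinshipMatrix:
    ids: np.ndarray
    matrix: np.ndarray  # dense symmetric phi, individuals in `ids` order

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("kinship matrix shape must match ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


def kinship_from_pedigree(ped: Pedigree) -> KinshipMatrix:
    """Kinship coefficients for every pair in the pedigree.

    Founders are assumed non-inbred and mutually unrelated; individuals in
    different families therefore have kinship exactly 0.
    """
    n = ped.n
    order = ped.topological_order()
    tab = ped.table
    idx = pd.Index(tab["iid"])
    father = np.full(n, -1)
    mother = np.full(n, -1)
    for i, (f, m) in enumerate(zip(tab["father"], tab["mother"])):
        if f != "":
            father[i] = idx.get_loc(f)
        if m != "":
            mother[i] = idx.get_loc(m)

    phi = np.zeros((n, n))
    for i in order:
        f, m = father[i], mother[i]
        if f < 0 and m < 0:
            phi[i, i] = 0.5
        else:
            # a missing parent contributes like an unrelated founder
            row_f = phi[f] if f >= 0 else 0.0
            row_m = phi[m] if m >= 0 else 0.0
            row = 0.5 * (row_f + row_m)
            phi[i, :] = row
            phi[:, i] = row
            phi[i, i] = 0.5 * (1.0 + (phi[f, m] if f >= 0 and m >= 0 else 0.0))
    return KinshipMatrix(ids=ped.ids.copy(), matrix=phi)


def relationship_matrix(kin: KinshipMatrix) -> np.ndarray:
    """Additive relationship matrix A = 2*phi, verified positive semidefinite.

    Raises :class:`PedigreeError` if the smallest eigenvalue is below -1e-8;
    tiny negative eigenvalues within that tolerance are clipped to zero.
    """
    a = 2.0 * kin.matrix
    w, v = np.linalg.eigh(a)
    if w.min() < -1e-8:
        raise PedigreeError(f"relationship matrix not PSD (min eigenvalue {w.min():.3g})")
    if w.min() < 0:
        w = np.clip(w, 0.0, None)
        a = (v * w) @ v.T
        a = 0.5 * (a + a.T)
    return a
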