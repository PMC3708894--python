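"""Analytic three-shell spherical head model for the EEG forward problem.

The scalp potential of a current dipole inside a set of concentric,
piecewise-homogeneous conducting shells has the classical Legendre-series
form

    V(r_e) = 1 / (4 pi sigma_1 R^2) * sum_n c_n (b/R)^(n-1)
             * [ n q_r P_n(cos a) + q_t sin(a) P_n'(cos a) ]

where b is the dipole eccentricity, R the outer (measurement) radius,
q_r / q_t the radial and tangential moment components in the plane spanned
by the dipole position and the electrode, and a the angle between the two.
The shell structure enters only through the per-degree amplification
factors c_n, obtained here by solving the small radial boundary-value
problem for each harmonic degree (continuity of potential and of radial
current at every interface, zero radial current at the outer surface).
For a single homogeneous sphere c_n reduces to the textbook (2n+1)/n.

Default geometry: brain 0.087 m / skull 0.092 m / scalp 0.100 m with
conductivities 0.33 / 0.0042 / 0.33 S/m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GeometryError(ValueError):
    """Raised when a source lies outside the innermost shell."""


@dataclass(frozen=True)
class ThreeShellModel:
    """Concentric-sphere volume conductor.

    Parameters
    ----------
    radii
        Outer radius of each shell, innermost first, metres.
    conductivities
        Conductivity of each shell, S/m, same order.
    n_terms
        Truncation order of the Legendre series. 200 terms bound the
        relative truncation error below ~1e-12 for eccentricities up to
        0.87 of the inner radius.
    """

    radii: tuple[float, ...] = (0.087, 0.092, 0.100)
    conductivities: tuple[float, ...] = (0.33, 0.0042, 0.33)
    n_terms: int = 200
    _cn: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.radii) != len(self.conductivities):
            raise ValueError("radii and conductivities must have equal length")
        if list(self.radii) != sorted(self.radii):
            raise ValueError("radii must be increasing (innermost first)")
        object.__setattr__(self, "_cn", self._shell_factors())

    @property
    def inner_radius(self) -> float:
        return self.radii[0]

    @property
    def outer_radius(self) -> float:
        return self.radii[-1]

    def _shell_factors(self) -> np.ndarray:
        """Per-degree amplification factors c_n, n = 1..n_terms.

        Solves, per degree, for the harmonic coefficients of each layer:
        layer 1 (source layer) has V = r^-(n+1) + A1 r^n, outer layers
        V = Aj r^n + Bj r^-(n+1); the returned factor is the scalp
        amplitude relative to the unbounded-medium primary term.
        Radii are scaled by the outer radius for conditioning.
        """
        m = len(self.radii)
        rho = np.asarray(self.radii) / self.outer_radius
        sig = np.asarray(self.conductivities)
        cn = np.empty(self.n_terms)
        for n in range(1, self.n_terms + 1):
            k = 2 * m - 1  # unknowns: A1, (Aj, Bj) j=2..m
            a = np.zeros((k, k))
            b = np.zeros(k)

            def col_a(j: int) -> int:  # index of Aj
                return 0 if j == 1 else 2 * j - 3

            def col_b(j: int) -> int:  # index of Bj (j >= 2)
                return 2 * j - 2

            row = 0
            for j in range(1, m):  # interface at rho[j-1] between layers j, j+1
                r = rho[j - 1]
                rn, rm = r ** n, r ** (-(n + 1))
                drn, drm = n * r ** (n - 1), -(n + 1) * r ** (-(n + 2))
                # potential continuity
                a[row, col_a(j)] += rn
                if j > 1:
                    a[row, col_b(j)] += rm
                else:
                    b[row] -= rm  # primary term, known
                a[row, col_a(j + 1)] -= rn
                a[row, col_b(j + 1)] -= rm
                row += 1
                # radial current continuity
                a[row, col_a(j)] += sig[j - 1] * drn
                if j > 1:
                    a[row, col_b(j)] += sig[j - 1] * drm
                else:
                    b[row] -= sig[j - 1] * drm
                a[row, col_a(j + 1)] -= sig[j] * drn
                a[row, col_b(j + 1)] -= sig[j] * drm
                row += 1
            # insulating outer boundary at rho = 1
            a[row, col_a(m)] += n
            if m > 1:
                a[row, col_b(m)] += -(n + 1)
            else:
                b[row] -= -(n + 1)
            row += 1

            sol = np.linalg.solve(a, b)
            if m > 1:
                cn[n - 1] = sol[col_a(m)] + sol[col_b(m)]
            else:
                cn[n - 1] = sol[col_a(1)] + 1.0
        return cn

    def potential(self, dipole_pos: np.ndarray, dipole_moment: np.ndarray,
                  electrodes: np.ndarray) -> np.ndarray:
        """Scalp potential of one dipole at the given electrode positions.

        Parameters
        ----------
        dipole_pos : (3,) metres, strictly inside the innermost shell.
        dipole_moment : (3,) ampere-metres.
        electrodes : (n, 3) metres; points are projected radially onto the
            outer surface (potentials are evaluated on the scalp sphere).

        Returns
        -------
        (n,) potentials in volts, zero-mean over the full sphere (no
        monopole term), i.e. effectively sphere-average referenced.
        """
        p = np.asarray(dipole_pos, dtype=float)
        q = np.asarray(dipole_moment, dtype=float)
        elec = np.atleast_2d(np.asarray(electrodes, dtype=float))
        b = np.linalg.norm(p)
        if b >= self.inner_radius:
            raise GeometryError(
                f"dipole at radius {b:.4f} m is not strictly inside the "
                f"innermost shell (radius {self.inner_radius:.4f} m)")
        R = self.outer_radius
        sigma1 = self.conductivities[0]
        e_hat = elec / np.linalg.norm(elec, axis=1, keepdims=True)

        if b < 1e-12:
            # only the n=1 term survives; the combination reduces to q.e_hat
            return self._cn[0] * (e_hat @ q) / (4 * np.pi * sigma1 * R ** 2)

        p_hat = p / b
        cosa = np.clip(e_hat @ p_hat, -1.0, 1.0)
        sina_t = e_hat - cosa[:, None] * p_hat[None, :]
        # t_hat * sin(a); keeping the sine absorbed avoids the sina=0 division
        q_t_sina = sina_t @ q
        q_r = float(p_hat @ q)

        ecc = b / R
        # Legendre recurrences, accumulated over degrees
        pn_m1 = np.ones_like(cosa)       # P_0
        pn = cosa.copy()                 # P_1
        dpn_m1 = np.zeros_like(cosa)     # P_0'
        dpn = np.ones_like(cosa)         # P_1'
        acc = np.zeros_like(cosa)
        ecc_pow = 1.0  # ecc^(n-1)
        for n in range(1, self.n_terms + 1):
            acc += self._cn[n - 1] * ecc_pow * (n * q_r * pn + q_t_sina * dpn)
            ecc_pow *= ecc
            pn_p1 = ((2 * n + 1) * cosa * pn - n * pn_m1) / (n + 1)
            dpn_p1 = dpn_m1 + (2 * n + 1) * pn
            pn_m1, pn = pn, pn_p1
            dpn_m1, dpn = dpn, dpn_p1
        return acc / (4 * np.pi * sigma1 * R ** 2)
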