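"""Projection-domain dual-energy decomposition into Al/PMMA thicknesses.

Each ray's pair of polyenergetic log attenuations (L80, L140) is inverted for
equivalent basis-material thicknesses (t_al, t_pmma) by a damped Newton
iteration on the 2x2 nonlinear system

    L_s(t) = -ln[ sum_E S_s(E) w(E) exp(-mu_Al(E) t_al - mu_PMMA(E) t_pmma)
                  / sum_E S_s(E) w(E) ]

whose Jacobian entries are the spectrum-effective attenuation coefficients of
the transmitted (hardened) beam.  A polynomial calibration path fitted on a
step-wedge grid is available as a fast alternative solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import ProjectionSet, require_paired
from .exceptions import DecompositionError, ValidationError
from .materials import Spectrum, detector_weights, linear_attenuation, mean_energy


@dataclass(frozen=True)
class DecompositionConfig:
    solver: str = "newton"
    tolerance: float = 1.0e-9  # log-attenuation units
    max_iterations: int = 60
    polynomial_order: int = 4
    allow_negative: bool = True

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValidationError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValidationError("need at least one iteration")
        if self.solver not in ("newton", "polynomial"):
            raise ValidationError(f"unknown solver {self.solver!r}")


@dataclass(frozen=True)
class BasisSinogram:
    """Al/PMMA equivalent-thickness sinograms (cm) with provenance."""

    t_al: np.ndarray
    t_pmma: np.ndarray
    angles: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.asarray(self.t_al).shape != np.asarray(self.t_pmma).shape:
            raise ValidationError("basis sinograms must share one shape")
        if not (
            np.all(np.isfinite(self.t_al)) and np.all(np.isfinite(self.t_pmma))
        ):
            raise ValidationError("basis sinograms must be finite")


class DualEnergyModel:
    """Forward model and solvers bound to one 80/140 kVp spectrum pair."""

    def __init__(
        self,
        spectrum_low: Spectrum,
        spectrum_high: Spectrum,
        detector: str = "ei",
        basis: tuple[str, str] = ("aluminum", "pmma"),
    ) -> None:
        self.spectrum_low = spectrum_low
        self.spectrum_high = spectrum_high
        self.basis = basis
        self._weights = []
        self._mu = []
        for sp in (spectrum_low, spectrum_high):
            w = sp.fluence * detector_weights(sp.energies, detector)
            self._weights.append(w / w.sum())
            self._mu.append(
                np.stack([linear_attenuation(b, sp.energies) for b in basis])
            )
        # conditioning guard on the monoenergetic-equivalent matrix
        m = np.array(
            [
                [linear_attenuation(b, mean_energy(sp)) for b in basis]
                for sp in (spectrum_low, spectrum_high)
            ]
        )
        self.mono_matrix = m
        if np.linalg.cond(m) > 1.0e6:
            raise DecompositionError(
                "spectrum pair is too ill-conditioned for two-material decomposition"
            )

    # -- forward ------------------------------------------------------------

    def forward_dual(self, t_al, t_pmma):
        """Predicted (L_low, L_high) log attenuations for thicknesses in cm."""
        t_al = np.asarray(t_al, float)
        t_pmma = np.asarray(t_pmma, float)
        out = []
        for w, mu in zip(self._weights, self._mu):
            expo = t_al[..., None] * mu[0] + t_pmma[..., None] * mu[1]
            out.append(-np.log(np.exp(-expo) @ w))
        return out[0], out[1]

    def _forward_and_jacobian(self, t_al, t_pmma):
        ls, js = [], []
        for w, mu in zip(self._weights, self._mu):
            trans = np.exp(-(t_al[..., None] * mu[0] + t_pmma[..., None] * mu[1])) * w
            total = trans.sum(axis=-1)
            ls.append(-np.log(total))
            # effective mu of the hardened transmitted beam = dL/dt
            js.append(
                ((trans @ mu[0]) / total, (trans @ mu[1]) / total)
            )
        jac = np.stack(
            [np.stack(js[0], axis=-1), np.stack(js[1], axis=-1)], axis=-2
        )  # (..., 2, 2)
        return np.stack(ls, axis=-1), jac

    # -- Newton solver -------------------------------------------------------

    def solve_ray(self, l_low, l_high, config: DecompositionConfig | None = None):
        """Invert (L_low, L_high) -> (t_al, t_pmma) by damped Newton iteration.

        Returns ``(t_al, t_pmma, converged)`` with the same broadcast shape as
        the inputs; non-converged elements keep their last iterate.
        """
        config = config or DecompositionConfig()
        l_low = np.asarray(l_low, float)
        l_high = np.asarray(l_high, float)
        if not (np.all(np.isfinite(l_low)) and np.all(np.isfinite(l_high))):
            raise ValidationError("log attenuations must be finite")
        target = np.stack(np.broadcast_arrays(l_low, l_high), axis=-1)
        shape = target.shape[:-1]

        mu_p_high = linear_attenuation(self.basis[1], mean_energy(self.spectrum_high))
        t_al = np.zeros(shape)
        t_pmma = np.clip(target[..., 1], 0.0, None) / mu_p_high
        ls, jac = self._forward_and_jacobian(t_al, t_pmma)
        resid = ls - target
        rnorm = np.abs(resid).max(axis=-1)
        for _ in range(config.max_iterations):
            active = rnorm > config.tolerance
            if not np.any(active):
                break
            det = jac[..., 0, 0] * jac[..., 1, 1] - jac[..., 0, 1] * jac[..., 1, 0]
            if np.any(np.abs(det) < 1e-300):
                raise DecompositionError("singular Jacobian in Newton solve")
            d_al = (jac[..., 1, 1] * resid[..., 0] - jac[..., 0, 1] * resid[..., 1]) / det
            d_pm = (-jac[..., 1, 0] * resid[..., 0] + jac[..., 0, 0] * resid[..., 1]) / det
            lam = np.where(active, 1.0, 0.0)
            for _ in range(8):  # halve the step where the residual grew
                t_al_try = t_al - lam * d_al
                t_pm_try = t_pmma - lam * d_pm
                ls_try, jac_try = self._forward_and_jacobian(t_al_try, t_pm_try)
                r_try = ls_try - target
                rn_try = np.abs(r_try).max(axis=-1)
                worse = active & (rn_try > rnorm)
                if not np.any(worse):
                    break
                lam = np.where(worse, lam / 2.0, lam)
            t_al, t_pmma = t_al_try, t_pm_try
            ls, jac, resid, rnorm = ls_try, jac_try, r_try, rn_try
        converged = rnorm <= config.tolerance
        if not config.allow_negative:
            t_al = np.clip(t_al, 0.0, None)
            t_pmma = np.clip(t_pmma, 0.0, None)
        return t_al, t_pmma, converged

    # -- sinogram-level ------------------------------------------------------

    def decompose(
        self,
        p_low: ProjectionSet,
        p_high: ProjectionSet,
        config: DecompositionConfig | None = None,
        chunk: int = 65536,
    ) -> BasisSinogram:
        """Elementwise solve over a paired dual-energy sinogram."""
        config = config or DecompositionConfig()
        require_paired(p_low, p_high)
        ll = p_low.line_integrals.reshape(-1)
        lh = p_high.line_integrals.reshape(-1)
        t_al = np.empty_like(ll)
        t_pm = np.empty_like(ll)
        n_bad = 0
        if config.solver == "polynomial":
            poly = self.calibrate_polynomial(order=config.polynomial_order)
            t_al, t_pm = poly(ll, lh)
        else:
            for k in range(0, ll.size, chunk):
                sl = slice(k, k + chunk)
                a, p, ok = self.solve_ray(ll[sl], lh[sl], config)
                t_al[sl], t_pm[sl] = a, p
                n_bad += int((~ok).sum())
        shape = p_low.line_integrals.shape
        return BasisSinogram(
            t_al=t_al.reshape(shape),
            t_pmma=t_pm.reshape(shape),
            angles=p_low.angles,
            provenance={
                "solver": config.solver,
                "tolerance": config.tolerance,
                "non_converged": n_bad,
                "kvp_pair": (p_low.kvp, p_high.kvp),
                "seeds": (p_low.seed, p_high.seed),
            },
        )

    # -- polynomial calibration path ----------------------------------------

    def calibrate_polynomial(
        self,
        t_al_max: float = 4.0,
        t_pmma_max: float = 30.0,
        n_steps: int = 12,
        order: int = 4,
    ):
        """Least-squares 2D polynomial inverse fitted on a step-wedge grid.

        Returns a callable ``(L_low, L_high) -> (t_al, t_pmma)`` carrying the
        maximum training residual as attribute ``max_residual_cm``.
        """
        powers = [
            (i, j) for i in range(order + 1) for j in range(order + 1) if i + j <= order
        ]
        if n_steps * n_steps < len(powers):
            raise ValidationError("polynomial order too high for wedge point count")
        ta, tp = np.meshgrid(
            np.linspace(0.0, t_al_max, n_steps), np.linspace(0.0, t_pmma_max, n_steps)
        )
        ll, lh = self.forward_dual(ta.ravel(), tp.ravel())

        def design(a, b):
            return np.stack([a**i * b**j for i, j in powers], axis=-1)

        A = design(ll, lh)
        coef_al, *_ = np.linalg.lstsq(A, ta.ravel(), rcond=None)
        coef_pm, *_ = np.linalg.lstsq(A, tp.ravel(), rcond=None)
        res = np.maximum(
            np.abs(A @ coef_al - ta.ravel()), np.abs(A @ coef_pm - tp.ravel())
        ).max()

        def poly(l_low, l_high):
            d = design(np.asarray(l_low, float), np.asarray(l_high, float))
            return d @ coef_al, d @ coef_pm

        poly.max_residual_cm = float(res)
        poly.powers = powers
        return poly
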