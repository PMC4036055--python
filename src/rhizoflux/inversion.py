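"""Flux estimation and piecewise-rate inversion of steady-state microprofiles.

Two layers live here:

* small estimators applied directly to a measured transect —
  :func:`estimate_flux` (Fick's first law over an interface window),
  :func:`estimate_rol` (radial oxygen loss at a root surface) and
  :func:`oxic_metrics` (penetration depth / oxic shell geometry);

* the profile-inversion model, :class:`ZoneRateModel`: fit a
  piecewise-constant net volumetric rate field R(z) to an observed
  steady-state profile by least squares against the forward
  reaction-diffusion solution, choosing the number of zones with nested
  F-tests.  This is the standard way net production/consumption zones are
  extracted from microsensor profiles in sediments and biofilms.

Sign conventions: fluxes are positive toward increasing position; rates
are consumption-positive, production-negative; radial oxygen loss is the
outward O2 flux at the root surface and is non-negative for a releasing
root segment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateZoneError,
    ProfileValidationError,
    UnsupportedAnalyteError,
)
from .profiles import (
    Analyte,
    BoundaryConditions,
    DiffusionCoefficients,
    DEFAULT_D,
    Geometry,
    MicroProfile,
    ZoneModel,
)
from .synthetic import SECONDS_PER_HOUR, _solve_fv

__all__ = [
    "FluxEstimate",
    "ROLEstimate",
    "OxicZoneMetrics",
    "estimate_flux",
    "estimate_rol",
    "oxic_metrics",
    "ZoneRateModel",
    "ZoneRateResults",
    "integrate_zone_rates",
]


def _diffusion_for(profile: MicroProfile, D) -> float:
    """Resolve a D argument (None, scalar, or DiffusionCoefficients)."""
    if D is None:
        D = DEFAULT_D
    if isinstance(D, DiffusionCoefficients):
        return D.get(profile.analyte)
    return float(D)


# --------------------------------------------------------------------------
# interface flux estimators


@dataclass(frozen=True)
class FluxEstimate:
    """Diffusive flux across an interface from a linear profile fit.

    ``flux`` is phi*D*|dC/dz| oriented toward increasing position,
    umol cm-2 h-1; ``slope``/``slope_se`` are the fitted concentration
    gradient (umol cm-4) and its standard error from ordinary least
    squares over ``window`` points on the inner side of the interface.
    """

    interface_position: float
    flux: float
    flux_se: float
    slope: float
    slope_se: float
    window: int
    analyte: Analyte
    d_cm2_s: float
    porosity: float


def estimate_flux(
    profile: MicroProfile,
    interface_index: int = 0,
    window: int = 3,
    D=None,
    porosity: float = 1.0,
    side: str | None = None,
) -> FluxEstimate:
    """Fick's-first-law flux at a grid point of a profile.

    An ordinary least-squares line is fitted to ``window`` consecutive
    points starting at ``interface_index`` on the inner side of the
    interface (toward increasing positions at the start of the transect,
    toward decreasing positions at its end), and

        J = -phi * D * dC/dz * 3600

    converts the gradient (per second) to umol cm-2 h-1, positive toward
    increasing position.  The flux standard error is propagated from the
    slope standard error of the fit; it is exactly zero for a perfectly
    linear window.

    Parameters
    ----------
    profile : MicroProfile
        Any solute profile (pH is rejected).
    interface_index : int
        Grid index of the interface; 0 is the reference interface.
    window : int
        Number of points in the fit, >= 2 (default 3: a 100 um window at
        the instrument-typical 50 um step).
    D : float or DiffusionCoefficients, optional
        Defaults to the 20 C free-water coefficient for the analyte.
    porosity : float
        Sediment porosity phi; 1.0 reproduces free-water arithmetic.
    side : {'forward', 'backward'}, optional
        Force the window direction; inferred from the index by default.
    """
    if not profile.analyte.is_solute:
        raise UnsupportedAnalyteError("cannot compute a diffusive flux from pH")
    if window < 2:
        raise ProfileValidationError("flux window must span at least 2 points")
    n = profile.n
    if side is None:
        side = "backward" if interface_index >= n - 1 else "forward"
    if side == "forward":
        sl = slice(interface_index, interface_index + window)
    elif side == "backward":
        sl = slice(interface_index - window + 1, interface_index + 1)
    else:
        raise ValueError("side must be 'forward' or 'backward'")
    z = profile.positions[sl]
    c = profile.concentrations[sl]
    if z.size < window or sl.start is not None and sl.start < 0:
        raise ProfileValidationError(
            f"window of {window} points not available at index {interface_index}"
        )

    if window == 2:
        slope = float((c[1] - c[0]) / (z[1] - z[0]))
        slope_se = 0.0
    else:
        fit = stats.linregress(z, c)
        slope = float(fit.slope)
        slope_se = float(fit.stderr) if np.isfinite(fit.stderr) else 0.0

    d = _diffusion_for(profile, D)
    scale = porosity * d * SECONDS_PER_HOUR
    return FluxEstimate(
        interface_position=float(profile.positions[interface_index]),
        flux=-scale * slope,
        flux_se=scale * slope_se,
        slope=slope,
        slope_se=slope_se,
        window=window,
        analyte=profile.analyte,
        d_cm2_s=d,
        porosity=porosity,
    )


@dataclass(frozen=True)
class ROLEstimate:
    """Radial oxygen loss: outward O2 flux at the root surface.

    ``rol`` is in umol O2 cm-2 root surface h-1 and is >= 0 for a
    releasing segment; a negative value (root side consuming O2 from the
    sediment) is reported as-is with ``inward_flux`` set.
    """

    rol: float
    rol_se: float
    flux: FluxEstimate
    apex_distance_mm: float | None
    inward_flux: bool


def estimate_rol(
    radial_o2: MicroProfile, D=None, window: int = 3, porosity: float = 1.0
) -> ROLEstimate:
    """Radial oxygen loss from a radial O2 profile (root surface at 0).

    The O2 gradient immediately outside the root is fitted over
    ``window`` points and converted with Fick's first law; the planar
    form is used, matching the per-cm2-root-surface units the field
    reports.  O2 falling away from the root gives a positive (outward)
    ROL.
    """
    if radial_o2.analyte is not Analyte.O2:
        raise UnsupportedAnalyteError("ROL is defined for O2 profiles")
    if radial_o2.geometry is not Geometry.RADIAL_FROM_ROOT:
        raise ProfileValidationError(
            "ROL needs a radial profile with position 0 at the root surface"
        )
    if radial_o2.n < window + 1:
        raise ProfileValidationError(
            f"need at least window+1 = {window + 1} points, got {radial_o2.n}"
        )
    est = estimate_flux(radial_o2, 0, window=window, D=D, porosity=porosity)
    return ROLEstimate(
        rol=est.flux,
        rol_se=est.flux_se,
        flux=est,
        apex_distance_mm=radial_o2.apex_distance_mm,
        inward_flux=est.flux < 0,
    )


# --------------------------------------------------------------------------
# oxic-zone geometry


@dataclass(frozen=True)
class OxicZoneMetrics:
    """Penetration depth and root-adjacent oxic shell of an O2 transect.

    ``penetration_depth_cm``: distance from the reference interface at
    which O2 first falls below the threshold (linear interpolation
    between the bracketing samples); equal to the domain length with
    ``not_reached`` set if O2 never drops below it.
    ``shell_thickness_cm``: extent of the contiguous above-threshold
    region adjacent to the root side of the transect.
    """

    penetration_depth_cm: float
    shell_thickness_cm: float
    threshold: float
    not_reached: bool = False
    never_oxic: bool = False


def _cross(z0, c0, z1, c1, thr):
    """Linear interpolation of the threshold crossing between two samples."""
    if c1 == c0:
        return z1
    return z0 + (thr - c0) * (z1 - z0) / (c1 - c0)


def oxic_metrics(
    o2_profile: MicroProfile, threshold: float = 1e-3, root_side: str | None = None
) -> OxicZoneMetrics:
    """Oxic-zone geometry of an O2 profile.

    Parameters
    ----------
    o2_profile : MicroProfile
    threshold : float
        Oxic/anoxic cutoff, umol cm-3; default 1e-3 (1 uM, a typical
        microsensor detection limit).
    root_side : {'start', 'end', None}
        Which end of the transect touches the root (for the shell
        metric). Inferred from the geometry by default: 'start' for
        radial profiles, 'end' for vertical ones running down onto a
        buried root.
    """
    if o2_profile.analyte is not Analyte.O2:
        raise UnsupportedAnalyteError("oxic metrics are defined for O2 profiles")
    if threshold <= 0:
        raise ProfileValidationError("threshold must be > 0")
    z = o2_profile.positions
    c = o2_profile.concentrations
    length = o2_profile.domain_length

    if np.all(c <= threshold):
        return OxicZoneMetrics(0.0, 0.0, threshold, never_oxic=True)

    # penetration depth from the reference interface (index 0)
    below = np.nonzero(c < threshold)[0]
    if below.size == 0:
        depth, not_reached = length, True
    else:
        i = int(below[0])
        if i == 0:
            depth, not_reached = 0.0, False
        else:
            depth = _cross(z[i - 1], c[i - 1], z[i], c[i], threshold) - z[0]
            not_reached = False

    # oxic shell adjacent to the root side
    if root_side is None:
        root_side = (
            "start" if o2_profile.geometry is Geometry.RADIAL_FROM_ROOT else "end"
        )
    if root_side == "end":
        z, c = z[::-1], c[::-1]  # walk away from the root
    elif root_side != "start":
        raise ValueError("root_side must be 'start', 'end', or None")
    if c[0] < threshold:
        shell = 0.0
    else:
        sub = np.nonzero(c < threshold)[0]
        if sub.size == 0:
            shell = length
        else:
            j = int(sub[0])
            shell = abs(_cross(z[j - 1], c[j - 1], z[j], c[j], threshold) - z[0])

    return OxicZoneMetrics(float(depth), float(shell), threshold, not_reached)


# --------------------------------------------------------------------------
# zone-rate inversion


class ZoneRateModel:
    """Piecewise-constant rate model for a steady-state microprofile.

    The observed profile is modelled as the steady state of
    ``phi*D*C'' = R(z)`` with R piecewise constant on k zones whose
    boundaries lie on the measurement grid, and with the measured end
    concentrations as boundary values.  For fixed boundaries the solution
    is linear in the zone rates, so rates are fitted by ordinary least
    squares against forward solutions; zone boundaries are found by
    exhaustive search over grid points (k <= 3) or greedy insertion with
    a local refinement sweep (k > 3); k itself is chosen as the smallest
    zone count whose improvement from one extra zone is not significant
    under a nested F-test.

    Parameters
    ----------
    profile : MicroProfile
        Uniformly gridded solute profile, >= 4 points.
    D : float or DiffusionCoefficients, optional
    porosity : float

    Examples
    --------
    >>> model = ZoneRateModel(profile)
    >>> res = model.fit(k_max=5, alpha=0.05)
    >>> res.zone_model.rates      # consumption positive, umol cm-3 h-1
    >>> print(res.summary())
    """

    def __init__(self, profile: MicroProfile, D=None, porosity: float = 1.0):
        if not profile.analyte.is_solute:
            raise UnsupportedAnalyteError("cannot invert rates from a pH profile")
        self.profile = profile
        self.d_cm2_s = _diffusion_for(profile, D)
        self.porosity = float(porosity)
        self._h = profile.spacing()
        self._z = profile.positions - profile.positions[0]
        self._responses = None

    @classmethod
    def from_dataframe(
        cls, frame, analyte: Analyte = Analyte.O2, D=None, porosity: float = 1.0, **kw
    ) -> "ZoneRateModel":
        """Build from a DataFrame with position_um / concentration_uM columns."""
        prof = MicroProfile(
            analyte=analyte,
            positions=np.asarray(frame["position_um"], dtype=float) * 1e-4,
            concentrations=np.asarray(frame["concentration_uM"], dtype=float) * 1e-3,
            **kw,
        )
        return cls(prof, D=D, porosity=porosity)

    # -- linear forward responses -----------------------------------------

    def _interval_responses(self) -> np.ndarray:
        """Discrete solution response to a unit rate on each grid interval.

        Column j solves the zero-Dirichlet system with a rate of
        1 umol cm-3 h-1 on interval [z_j, z_{j+1}]; any zone layout's
        design column is a contiguous sum of these, taken from prefix
        sums.
        """
        if self._responses is not None:
            return self._responses
        n = self.profile.n
        h = self._h
        # cell integrals of a unit rate (per second) on interval j:
        # half a cell to node j, half to node j+1
        q = np.zeros((n, n - 1))
        half = (h / 2.0) / SECONDS_PER_HOUR
        idx = np.arange(n - 1)
        q[idx, idx] += half
        q[idx + 1, idx] += half
        bc = BoundaryConditions.dirichlet(0.0, 0.0)
        G = _solve_fv(n, h, self.porosity * self.d_cm2_s, q, bc)
        # prefix sums: P[:, i] = sum of columns j < i
        P = np.zeros((n, n))
        np.cumsum(G, axis=1, out=P[:, 1:])
        self._responses = P
        return P

    def _design(self, cuts: tuple[int, ...]) -> np.ndarray:
        """Design matrix for zone boundaries at grid indices (0, *cuts, n-1).

        The first two columns are the homogeneous (zero-rate) solutions —
        a constant and a linear ramp — so the boundary concentrations are
        estimated together with the rates instead of being pinned to the
        two noisy end measurements; the remaining columns are the forward
        responses of the candidate zones.
        """
        P = self._interval_responses()
        edges = (0, *cuts, self.profile.n - 1)
        cols = [np.ones_like(self._z), self._z / self._z[-1]]
        cols += [P[:, b] - P[:, a] for a, b in zip(edges, edges[1:])]
        return np.stack(cols, axis=1)

    def _fit_rates(self, cuts: tuple[int, ...], y: np.ndarray):
        X = self._design(cuts)
        coef, rss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            edges = (0, *cuts, self.profile.n - 1)
            raise DegenerateZoneError(
                f"rank-deficient fit: zone grid indices {edges} give "
                f"collinear responses"
            )
        resid = y - X @ coef
        return coef, float(resid @ resid), X

    def _best_layout(self, k: int, y: np.ndarray):
        """Best boundary layout for a given zone count."""
        n = self.profile.n
        interior = range(1, n - 1)
        if k == 1:
            candidates = [()]
        elif k <= 3:
            candidates = itertools.combinations(interior, k - 1)
        else:
            # greedy insertion on top of the best (k-1)-zone layout,
            # then one sweep of single-cut local refinement
            base, _, _ = self._best_layout(k - 1, y)
            best = None
            for c in interior:
                if c in base:
                    continue
                cuts = tuple(sorted((*base, c)))
                try:
                    _, rss, _ = self._fit_rates(cuts, y)
                except DegenerateZoneError:
                    continue
                if best is None or rss < best[1]:
                    best = (cuts, rss)
            if best is None:
                raise DegenerateZoneError(f"no feasible {k}-zone layout")
            cuts = list(best[0])
            for i in range(len(cuts)):
                lo = cuts[i - 1] + 1 if i > 0 else 1
                hi = cuts[i + 1] if i + 1 < len(cuts) else n - 1
                for c in range(lo, hi):
                    trial = tuple(cuts[:i] + [c] + cuts[i + 1 :])
                    try:
                        _, rss, _ = self._fit_rates(trial, y)
                    except DegenerateZoneError:
                        continue
                    if rss < best[1]:
                        best = (trial, rss)
                        cuts = list(trial)
            candidates = [best[0]]

        best = None
        for cuts in candidates:
            cuts = tuple(cuts)
            try:
                coef, rss, _ = self._fit_rates(cuts, y)
            except DegenerateZoneError:
                continue
            if best is None or rss < best[1]:
                best = (cuts, rss, coef)
        if best is None:
            raise DegenerateZoneError(f"no feasible {k}-zone layout")
        return best

    # -- fitting -----------------------------------------------------------

    def fit(self, k_max: int = 5, alpha: float = 0.05, boundaries=None) -> "ZoneRateResults":
        """Fit zone rates, selecting the zone count by nested F-tests.

        Parameters
        ----------
        k_max : int
            Largest zone count considered; needs ``n >= 2*k_max + 2``
            points.
        alpha : float
            Significance level of the F-test comparing k against k+1
            zones; the selected k is the smallest whose improvement from
            an extra zone is non-significant.
        boundaries : sequence of float, optional
            Fix the zone boundaries (cm, on the grid) instead of
            searching; only the rates are then estimated.
        """
        prof = self.profile
        n = prof.n
        y = prof.concentrations.astype(float)

        if boundaries is not None:
            cuts = tuple(self._grid_index(b) for b in np.asarray(boundaries)[1:-1])
            coef, rss, _ = self._fit_rates(cuts, y)
            return self._results(cuts, coef, rss, alpha, selection=[])

        if n < 2 * k_max + 2:
            raise ProfileValidationError(
                f"need at least 2*k_max+2 = {2 * k_max + 2} points for k_max={k_max}"
            )
        # perfect-fit floor: below this RSS the F statistic is numerical noise
        tol = n * (1e-10 * max(np.max(np.abs(y)), 1e-300)) ** 2

        fits = {}
        selection = []
        chosen = None
        for k in range(1, k_max + 1):
            fits[k] = self._best_layout(k, y)
            if fits[k][1] <= tol:
                chosen = k
                break
            if k == k_max:
                chosen = k_max
                break
            fits[k + 1] = self._best_layout(k + 1, y)
            rss_k, rss_k1 = fits[k][1], fits[k + 1][1]
            p_k1 = 2 * (k + 1) + 1  # baseline level/slope + rates + interior cuts
            df2 = n - p_k1
            if df2 <= 0:
                chosen = k
                break
            F = max(rss_k - rss_k1, 0.0) / 2.0 / max(rss_k1 / df2, 1e-300)
            # the extra boundary was searched over every free grid point, so
            # the improvement is a best-of-m statistic; Bonferroni-adjust the
            # nested F-test p-value for that selection multiplicity
            m = max((n - 2) - (k - 1), 1)
            pval = float(min(1.0, m * stats.f.sf(F, 2, df2)))
            selection.append({"k": k, "F": F, "p": pval, "rss_k": rss_k, "rss_k1": rss_k1})
            if pval >= alpha:
                chosen = k
                break
        cuts, rss, coef = fits[chosen]
        return self._results(cuts, coef, rss, alpha, selection)

    def _grid_index(self, z: float) -> int:
        i = int(round((z - self.profile.positions[0]) / self._h))
        if abs(self.profile.positions[0] + i * self._h - z) > 1e-6 * self._h + 1e-12:
            raise ProfileValidationError(
                f"zone boundary {z} does not lie on the measurement grid"
            )
        return i

    def _results(self, cuts, coef, rss, alpha, selection) -> "ZoneRateResults":
        prof = self.profile
        n = prof.n
        X = self._design(tuple(cuts))
        k = len(coef) - 2
        p = 2 * k + 1  # baseline level/slope + k rates + (k-1) interior cuts
        dof = max(n - p, 1)
        sigma2 = rss / dof
        try:
            cov = sigma2 * np.linalg.inv(X.T @ X)
        except np.linalg.LinAlgError as exc:
            raise DegenerateZoneError("singular normal equations") from exc
        edges_idx = (0, *cuts, n - 1)
        boundaries = prof.positions[list(edges_idx)]
        return ZoneRateResults(
            model=self,
            zone_model=ZoneModel(boundaries, coef[2:]),
            rates_se=np.sqrt(np.diag(cov)[2:]),
            rss=rss,
            dof=dof,
            fitted=X @ coef,
            alpha=alpha,
            selection_path=selection,
        )


@dataclass
class ZoneRateResults:
    """Results of a :class:`ZoneRateModel` fit.

    Attributes
    ----------
    zone_model : ZoneModel
        Selected boundaries (cm) and rates (umol cm-3 h-1, consumption
        positive).
    rates_se : ndarray
        Standard errors of the zone rates from the least-squares
        covariance.
    rss, dof : float, int
        Residual sum of squares and residual degrees of freedom.
    fitted : ndarray
        Fitted concentrations on the measurement grid.
    selection_path : list of dict
        F-statistics and p-values of the k vs k+1 comparisons walked
        during model selection.
    """

    model: ZoneRateModel
    zone_model: ZoneModel
    rates_se: np.ndarray
    rss: float
    dof: int
    fitted: np.ndarray
    alpha: float
    selection_path: list

    @property
    def k(self) -> int:
        return self.zone_model.k

    @property
    def rates(self) -> np.ndarray:
        return self.zone_model.rates

    def conf_int(
        self, level: float = 0.95, boundary_uncertainty: bool = True
    ) -> np.ndarray:
        """Per-zone rate confidence intervals, shape (k, 2).

        With ``boundary_uncertainty`` (default) the interval is the
        envelope of t-intervals over every zone layout whose residual
        sum of squares is statistically indistinguishable from the
        optimum (profile-likelihood cutoff at ``level`` for the searched
        boundary).  Zone boundaries are estimated, not known, and the
        conditional least-squares covariance alone understates the rate
        uncertainty; the envelope restores calibrated coverage.
        """
        tval = stats.t.ppf(0.5 + level / 2.0, self.dof)
        half = tval * self.rates_se
        ci = np.column_stack([self.rates - half, self.rates + half])
        if not boundary_uncertainty or self.k == 1:
            return ci

        m = self.model
        n = m.profile.n
        y = m.profile.concentrations
        cutoff = self.rss * (1.0 + stats.f.ppf(level, 1, self.dof) / self.dof)
        sel = tuple(m._grid_index(b) for b in self.zone_model.boundaries[1:-1])
        if self.k <= 3:
            layouts = itertools.combinations(range(1, n - 1), self.k - 1)
        else:
            # vary one cut at a time around the selected layout
            layouts = []
            for i in range(len(sel)):
                lo = sel[i - 1] + 1 if i > 0 else 1
                hi = sel[i + 1] if i + 1 < len(sel) else n - 1
                for c in range(lo, hi):
                    layouts.append(tuple(sel[:i] + (c,) + sel[i + 1 :]))
        for cuts in layouts:
            try:
                coef, rss, X = m._fit_rates(tuple(cuts), y)
            except DegenerateZoneError:
                continue
            if rss > cutoff:
                continue
            se = np.sqrt(np.diag((rss / self.dof) * np.linalg.inv(X.T @ X))[2:])
            ci[:, 0] = np.minimum(ci[:, 0], coef[2:] - tval * se)
            ci[:, 1] = np.maximum(ci[:, 1], coef[2:] + tval * se)
        return ci

    def integrated_rate(self) -> float:
        """Depth-integrated net rate, sum(R_i h_i), umol cm-2 h-1."""
        return self.zone_model.depth_integrated()

    def boundary_fluxes(self) -> tuple[float, float]:
        """Diffusive fluxes (umol cm-2 h-1, toward +z) at the two ends of
        the fitted solution.

        Computed as the discrete face flux corrected by the half-cell
        rate integral, which makes the conservation identity
        ``J(0) - J(L) == integrated_rate()`` exact for the fitted model.
        """
        prof = self.model.profile
        h = self.model._h
        phi_d = self.model.porosity * self.model.d_cm2_s * SECONDS_PER_HOUR
        c = self.fitted
        zm = self.zone_model
        z0, zL = prof.positions[0], prof.positions[-1]
        j0 = -phi_d * (c[1] - c[0]) / h + zm.integral(z0, z0 + h / 2.0)
        jL = -phi_d * (c[-1] - c[-2]) / h - zm.integral(zL - h / 2.0, zL)
        return float(j0), float(jL)

    def predict(self) -> np.ndarray:
        """Fitted concentrations on the measurement grid."""
        return self.fitted.copy()

    def summary(self) -> str:
        """Plain-text summary table in the spirit of a regression report."""
        prof = self.model.profile
        lines = [
            "Zone-rate inversion results",
            "===========================",
            f"analyte: {prof.analyte.value}   points: {prof.n}   "
            f"grid: {self.model._h * 1e4:.0f} um",
            f"D = {self.model.d_cm2_s:.3e} cm2/s   porosity = {self.model.porosity}",
            f"zones selected: {self.k} (alpha = {self.alpha})   "
            f"RSS = {self.rss:.4e}   dof = {self.dof}",
            "",
            f"{'z_start_cm':>11} {'z_end_cm':>9} {'rate':>10} {'se':>9}  "
            f"(umol cm-3 h-1, consumption > 0)",
        ]
        zm = self.zone_model
        for i in range(self.k):
            lines.append(
                f"{zm.boundaries[i]:>11.4f} {zm.boundaries[i + 1]:>9.4f} "
                f"{zm.rates[i]:>10.4f} {self.rates_se[i]:>9.4f}"
            )
        j0, jl = self.boundary_fluxes()
        lines += [
            "",
            f"depth-integrated rate: {self.integrated_rate():+.4f} umol cm-2 h-1",
            f"boundary fluxes: J(0) = {j0:+.4f}, J(L) = {jl:+.4f} umol cm-2 h-1",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot observed vs fitted profile with the zone structure."""
        import matplotlib.pyplot as plt

        prof = self.model.profile
        if ax is None:
            _, ax = plt.subplots()
        z_mm = prof.positions * 10.0
        ax.plot(z_mm, prof.concentrations * 1e3, "o", ms=3, label="observed")
        ax.plot(z_mm, self.fitted * 1e3, "-", label=f"fitted (k={self.k})")
        for b in self.zone_model.boundaries[1:-1]:
            ax.axvline(b * 10.0, color="0.7", lw=0.8)
        ax.set_xlabel("position (mm)")
        ax.set_ylabel(f"{prof.analyte.value} (uM)")
        ax.legend()
        return ax


def integrate_zone_rates(zones: ZoneModel) -> float:
    """Depth-integrate a zone model: sum(R_i * h_i), umol cm-2 h-1.

    Converts volumetric zone rates into the areal rates the field
    reports for interfaces (e.g. per cm2 of sediment or root surface).
    """
    return zones.depth_integrated()
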