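"""Input-oriented data envelopment analysis (DEA).

DEA measures the relative efficiency of decision-making units (DMUs) that
convert multiple inputs into multiple outputs.  For DMU 0 the input-oriented
envelopment problem asks for the largest equiproportional contraction of its
inputs that a convex combination of observed DMUs can still dominate:

    min  θ
    s.t. Σ_j λ_j x_ij ≤ θ x_i0   for every input i
         Σ_j λ_j y_rj ≥ y_r0     for every output r
         λ_j ≥ 0
         (VRS adds Σ_j λ_j = 1; NIRS adds Σ_j λ_j ≤ 1)

θ under constant returns to scale (CRS, the CCR model) is the overall
efficiency; θ under variable returns to scale (VRS, the BCC model) is the
technical efficiency; their ratio is the scale efficiency.  A second phase
maximizes the residual input/output slacks at the optimal θ (the ε-free
two-phase construction), and the CRS/NIRS/VRS comparison classifies returns
to scale.

The model/results split follows the statsmodels convention:
``DEA(inputs, outputs).fit()`` returns a :class:`DEAResults` carrying the
scores, slacks, peer weights and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .panel import RESOURCES, UTILIZATION, Panel

FRONTIERS = ("crs", "vrs", "nirs")

#: default tolerance on θ ties and (rescaled) slack-zero tests
DEFAULT_TOL = 1e-6


class DEAError(ValueError):
    """Invalid envelopment problem."""


class DEASolverError(RuntimeError):
    """The LP solver failed; carries the solver status message."""


def _as_dmu_matrix(arr, name: str) -> np.ndarray:
    a = np.asarray(arr, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2:
        raise DEAError(f"{name} must be a 2-d array (DMUs × variables)")
    if not np.all(np.isfinite(a)) or np.any(a < 0):
        raise DEAError(f"{name} must be non-negative and finite")
    return a


class DEA:
    """Input-oriented envelopment model.

    Parameters
    ----------
    inputs : array-like, shape (n_dmus, m)
        Non-negative input quantities, one row per DMU.
    outputs : array-like, shape (n_dmus, s)
        Non-negative output quantities, one row per DMU.
    dmu_labels : sequence of str, optional
        Labels for reporting; defaults to ``DMU_0 .. DMU_{n-1}``.

    Each DMU must have at least one strictly positive input and one
    strictly positive output.  Rows are internally rescaled to mean one per
    variable before solving — radial scores are invariant to units, and the
    rescaling keeps the LPs well conditioned when outputs (e.g. consultation
    counts) are orders of magnitude larger than inputs; slacks are reported
    back in original units.
    """

    def __init__(self, inputs, outputs, dmu_labels=None, orientation: str = "input"):
        if orientation != "input":
            raise NotImplementedError("only input orientation is supported")
        self.orientation = orientation
        X = _as_dmu_matrix(inputs, "inputs")
        Y = _as_dmu_matrix(outputs, "outputs")
        if X.shape[0] != Y.shape[0]:
            raise DEAError("inputs and outputs must have the same number of DMUs")
        if X.shape[0] < 1:
            raise DEAError("at least one DMU is required")
        if np.any(X.sum(axis=1) <= 0):
            raise DEAError("every DMU needs at least one strictly positive input")
        if np.any(Y.sum(axis=1) <= 0):
            raise DEAError("every DMU needs at least one strictly positive output")
        self.inputs = X
        self.outputs = Y
        self.n_dmus, self.m_inputs = X.shape
        self.s_outputs = Y.shape[1]
        if dmu_labels is None:
            dmu_labels = [f"DMU_{j}" for j in range(self.n_dmus)]
        if len(dmu_labels) != self.n_dmus:
            raise DEAError("dmu_labels length must match the number of DMUs")
        self.dmu_labels = [str(x) for x in dmu_labels]
        # per-variable scales (mean over DMUs); zero-variance-at-zero rows keep scale 1
        xs = X.mean(axis=0)
        ys = Y.mean(axis=0)
        self._xscale = np.where(xs > 0, xs, 1.0)
        self._yscale = np.where(ys > 0, ys, 1.0)
        self._Xs = X / self._xscale
        self._Ys = Y / self._yscale

    # -- linear programs ---------------------------------------------------

    def _phase1(self, j0: int, frontier: str) -> tuple[float, np.ndarray]:
        """Radial LP for DMU ``j0``: returns (θ, λ)."""
        n, m, s = self.n_dmus, self.m_inputs, self.s_outputs
        X, Y = self._Xs.T, self._Ys.T  # (m, n), (s, n)
        # variables: [θ, λ_1..λ_n]
        c = np.zeros(1 + n)
        c[0] = 1.0
        A_ub = np.zeros((m + s, 1 + n))
        b_ub = np.zeros(m + s)
        A_ub[:m, 0] = -X[:, j0]
        A_ub[:m, 1:] = X
        A_ub[m:, 1:] = -Y
        b_ub[m:] = -Y[:, j0]
        A_eq = b_eq = None
        if frontier == "vrs":
            A_eq = np.zeros((1, 1 + n))
            A_eq[0, 1:] = 1.0
            b_eq = np.ones(1)
        elif frontier == "nirs":
            row = np.zeros((1, 1 + n))
            row[0, 1:] = 1.0
            A_ub = np.vstack([A_ub, row])
            b_ub = np.append(b_ub, 1.0)
        elif frontier != "crs":
            raise DEAError(f"unknown frontier {frontier!r}")
        bounds = [(None, None)] + [(0.0, None)] * n
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                      bounds=bounds, method="highs")
        if res.status != 0:
            raise DEASolverError(
                f"phase-1 LP failed for DMU {self.dmu_labels[j0]!r} "
                f"({frontier}): status {res.status}, {res.message}"
            )
        theta = float(res.x[0])
        lam = np.maximum(res.x[1:], 0.0)
        if theta > 1.0:
            if theta > 1.0 + 1e-7:
                raise DEASolverError(
                    f"θ = {theta} > 1 for DMU {self.dmu_labels[j0]!r}; "
                    "the self-referencing solution should always be feasible"
                )
            theta = 1.0
        if theta <= 0:
            raise DEASolverError(
                f"non-positive θ = {theta} for DMU {self.dmu_labels[j0]!r}"
            )
        return theta, lam

    def _phase2(self, j0: int, frontier: str, theta: float):
        """Slack-maximization LP at fixed θ.

        Returns (input_slacks, output_slacks, λ) with slacks in the
        rescaled (mean-one) units; callers convert back.
        """
        n, m, s = self.n_dmus, self.m_inputs, self.s_outputs
        X, Y = self._Xs.T, self._Ys.T
        # variables: [λ (n), s⁻ (m), s⁺ (s)]
        nv = n + m + s
        c = np.zeros(nv)
        c[n:] = -1.0  # maximize slack sum
        A_eq = np.zeros((m + s, nv))
        A_eq[:m, :n] = X
        A_eq[:m, n:n + m] = np.eye(m)
        A_eq[m:, :n] = Y
        A_eq[m:, n + m:] = -np.eye(s)
        b_eq = np.concatenate([theta * X[:, j0], Y[:, j0]])
        A_ub = b_ub = None
        if frontier == "vrs":
            row = np.zeros((1, nv))
            row[0, :n] = 1.0
            A_eq = np.vstack([A_eq, row])
            b_eq = np.append(b_eq, 1.0)
        elif frontier == "nirs":
            A_ub = np.zeros((1, nv))
            A_ub[0, :n] = 1.0
            b_ub = np.ones(1)
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                      bounds=[(0.0, None)] * nv, method="highs")
        if res.status != 0:
            raise DEASolverError(
                f"phase-2 LP failed for DMU {self.dmu_labels[j0]!r} "
                f"({frontier}): status {res.status}, {res.message}"
            )
        lam = np.maximum(res.x[:n], 0.0)
        s_in = np.maximum(res.x[n:n + m], 0.0)
        s_out = np.maximum(res.x[n + m:], 0.0)
        return s_in, s_out, lam

    # -- public API --------------------------------------------------------

    def solve_envelopment(self, dmu_index: int, frontier: str = "crs"):
        """Optimal radial contraction θ and peer weights λ for one DMU."""
        self._check_index(dmu_index)
        return self._phase1(dmu_index, frontier)

    def solve_slacks(self, dmu_index: int, theta: float, frontier: str = "crs"):
        """Maximal slacks at the phase-1 optimum, in original units."""
        self._check_index(dmu_index)
        s_in, s_out, lam = self._phase2(dmu_index, frontier, theta)
        return s_in * self._xscale, s_out * self._yscale, lam

    def _check_index(self, j0: int) -> None:
        if not 0 <= j0 < self.n_dmus:
            raise IndexError(f"dmu_index {j0} out of range [0, {self.n_dmus})")

    def fit(self, tol: float = DEFAULT_TOL, slack_frontier: str = "crs") -> "DEAResults":
        """Solve all frontiers for every DMU.

        Parameters
        ----------
        tol : float
            Tolerance for θ ties (efficiency, returns-to-scale comparison)
            and for the slack-zero test in rescaled units.
        slack_frontier : {"crs", "vrs"}
            Which model's phase-2 slacks to report.  The CRS default
            matches reporting conventions in which a technically efficient
            DMU can still show non-zero (scale-related) slack.
        """
        if slack_frontier not in ("crs", "vrs"):
            raise DEAError("slack_frontier must be 'crs' or 'vrs'")
        n = self.n_dmus
        theta = {f: np.empty(n) for f in FRONTIERS}
        peers = {f: np.empty((n, n)) for f in FRONTIERS}
        s_in = np.empty((n, self.m_inputs))
        s_out = np.empty((n, self.s_outputs))
        lam_slack = np.empty((n, n))
        for j in range(n):
            for f in FRONTIERS:
                theta[f][j], peers[f][j] = self._phase1(j, f)
            si, so, lam = self._phase2(j, slack_frontier, theta[slack_frontier][j])
            s_in[j], s_out[j], lam_slack[j] = si, so, lam
        # clamp tiny solver noise so that crs ≤ nirs ≤ vrs holds exactly
        theta["nirs"] = np.clip(theta["nirs"], theta["crs"], None)
        theta["vrs"] = np.clip(theta["vrs"], theta["nirs"], None)
        return DEAResults(self, theta, peers, s_in, s_out, lam_slack,
                          tol=tol, slack_frontier=slack_frontier)


def returns_to_scale(theta_crs: float, theta_vrs: float, theta_nirs: float,
                     tol: float = DEFAULT_TOL) -> str:
    """Classify returns to scale from the three frontier scores.

    Constant when CRS and VRS scores tie; otherwise the NIRS score decides:
    NIRS = VRS places the DMU on the non-increasing part of the frontier
    (decreasing returns), NIRS = CRS < VRS on the increasing part.
    """
    for name, t in (("crs", theta_crs), ("vrs", theta_vrs), ("nirs", theta_nirs)):
        if not 0 < t <= 1 + tol:
            raise ValueError(f"theta_{name} must lie in (0, 1]; got {t}")
    if abs(theta_crs - theta_vrs) <= tol:
        return "constant"
    if abs(theta_nirs - theta_vrs) <= tol:
        return "decreasing"
    return "increasing"


class DEAResults:
    """Fitted efficiencies, slacks and peers for every DMU.

    Attributes
    ----------
    overall : ndarray
        θ under CRS (overall efficiency, CCR score).
    technical : ndarray
        θ under VRS (technical efficiency, BCC score).
    scale : ndarray
        overall / technical; 1 marks the most productive scale size.
    rts : list of str
        Returns-to-scale label per DMU (constant/increasing/decreasing).
    input_slacks, output_slacks : ndarray
        Phase-2 slacks in original units, from the ``slack_frontier`` model.
    efficient : ndarray of bool
        Overall efficiency within ``tol`` of 1 and all slacks zero within
        ``tol`` at the data's per-variable scale.
    """

    def __init__(self, model: DEA, theta: dict, peers: dict,
                 input_slacks, output_slacks, slack_peers,
                 tol: float, slack_frontier: str):
        self.model = model
        self.tol = tol
        self.slack_frontier = slack_frontier
        self.overall = theta["crs"]
        self.technical = theta["vrs"]
        self.nirs = theta["nirs"]
        self.scale = self.overall / self.technical
        self.peer_weights = peers
        self.input_slacks = input_slacks
        self.output_slacks = output_slacks
        self.slack_peers = slack_peers
        self.rts = [
            returns_to_scale(c, v, ni, tol)
            for c, v, ni in zip(self.overall, self.technical, self.nirs)
        ]
        scaled_in = input_slacks / model._xscale
        scaled_out = output_slacks / model._yscale
        self.efficient = (
            (self.overall >= 1.0 - tol)
            & (scaled_in.max(axis=1, initial=0.0) <= tol)
            & (scaled_out.max(axis=1, initial=0.0) <= tol)
        )

    def to_frame(self, input_names=None, output_names=None) -> pd.DataFrame:
        """Long table: one row per DMU with scores, RTS, slacks, status."""
        m, s = self.model.m_inputs, self.model.s_outputs
        input_names = list(input_names) if input_names else [f"input_{i}" for i in range(m)]
        output_names = list(output_names) if output_names else [f"output_{r}" for r in range(s)]
        df = pd.DataFrame(
            {
                "dmu": self.model.dmu_labels,
                "overall_efficiency": self.overall,
                "technical_efficiency": self.technical,
                "scale_efficiency": self.scale,
                "returns_to_scale": self.rts,
            }
        )
        for i, name in enumerate(input_names):
            df[f"slack_{name}"] = self.input_slacks[:, i]
        for r, name in enumerate(output_names):
            df[f"slack_{name}"] = self.output_slacks[:, r]
        df["status"] = np.where(self.efficient, "efficient", "inefficient")
        return df

    def summary(self, input_names=None, output_names=None) -> str:
        """Plain-text summary table (3-decimal scores, 3-decimal slacks)."""
        df = self.to_frame(input_names, output_names)
        with pd.option_context("display.float_format", lambda v: f"{v:.3f}",
                               "display.width", 160, "display.max_columns", 40):
            body = df.to_string(index=False)
        head = (
            f"Input-oriented DEA, {self.model.n_dmus} DMUs, "
            f"{self.model.m_inputs} inputs, {self.model.s_outputs} outputs; "
            f"slacks from {self.slack_frontier.upper()} phase 2, tol={self.tol:g}"
        )
        return head + "\n" + body


# -- panel-level schemes ---------------------------------------------------

DMU_SCHEMES = ("years_as_dmus_on_totals", "regions_as_dmus_per_year")


def run_dea(
    panel: Panel,
    dmu_scheme: str = "years_as_dmus_on_totals",
    inputs=RESOURCES,
    outputs=UTILIZATION,
    tol: float = DEFAULT_TOL,
    slack_frontier: str = "crs",
):
    """Run DEA on a health-resource panel.

    ``years_as_dmus_on_totals`` treats each year's province totals as one
    DMU (the by-year report); ``regions_as_dmus_per_year`` solves an
    independent cross-section per year with regions as DMUs (the by-region
    report) and returns ``{year: DEAResults}``.
    """
    if not panel.is_complete:
        raise DEAError("panel is incomplete: every region × year is required")
    if dmu_scheme == "years_as_dmus_on_totals":
        tot = panel.totals_frame()
        model = DEA(
            tot[list(inputs)].to_numpy(),
            tot[list(outputs)].to_numpy(),
            dmu_labels=[str(y) for y in tot["year"]],
        )
        return model.fit(tol=tol, slack_frontier=slack_frontier)
    if dmu_scheme == "regions_as_dmus_per_year":
        out = {}
        for year in panel.years:
            sl = panel.year_slice(year)
            model = DEA(
                sl[list(inputs)].to_numpy(),
                sl[list(outputs)].to_numpy(),
                dmu_labels=sl["region_id"].tolist(),
            )
            out[year] = model.fit(tol=tol, slack_frontier=slack_frontier)
        return out
    raise DEAError(f"dmu_scheme must be one of {DMU_SCHEMES}")


def dea_by_year_table(panel: Panel, **kwargs) -> pd.DataFrame:
    """By-year report: province totals as DMUs, with per-variable slacks."""
    res = run_dea(panel, "years_as_dmus_on_totals", **kwargs)
    df = res.to_frame(input_names=RESOURCES, output_names=UTILIZATION)
    return df.rename(columns={"dmu": "year"})


def dea_by_region_table(panel: Panel, **kwargs) -> pd.DataFrame:
    """By-region report: per-year cross-sections, long format."""
    per_year = run_dea(panel, "regions_as_dmus_per_year", **kwargs)
    frames = []
    for year, res in per_year.items():
        df = res.to_frame()[
            ["dmu", "overall_efficiency", "technical_efficiency",
             "scale_efficiency", "returns_to_scale", "status"]
        ].rename(columns={"dmu": "region_id"})
        df.insert(1, "year", year)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
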