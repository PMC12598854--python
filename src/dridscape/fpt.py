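"""First-passage-time kinetics by spectral solution of the master equation.

For a transition to a product set A from a reactant set B, the product
states are made absorbing: the occupation probabilities of the surviving
states I u B (I = S \\ (A u B)) evolve under dP/dt = M P, where M carries
the inter-state rates off-diagonal and total escape rates (including flux
into A) on the diagonal.  Eigendecomposition of -M gives the first-passage
time distribution as a mixture of exponential decay modes,

    p(t) = sum_l nu_l A_l exp(-nu_l t),

with nu_l > 0 the eigenvalues and amplitudes A_l fixed by the eigenvectors
and the initial distribution.  On a logarithmic time axis (y = ln t / 1 ps)

    P(y) = sum_l nu_l exp(y - nu_l e^y) A_l,

whose peaks mark the characteristic time scales of competing pathways; the
mean first-passage time is sum_l A_l / nu_l.

File conventions follow the PATHSAMPLE workflow: endpoint sets come from
``min.A`` / ``min.B`` (count on the first line, 1-based ids after), the
B->A distribution is written to ``waitlnpdfAB`` and the reverse to
``waitlnpdfBA`` as two-column text (ln t, P), and WAITPDFPRINT mode writes
per-start-state ``waitlnpdfA.ID`` / ``peaksA.ID`` files.  All times are in
ps, so the first column exponentiates to ps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from .network import KineticNetwork

__all__ = [
    "EndpointSets",
    "MasterOperator",
    "FPTDistribution",
    "read_min_file",
    "write_min_file",
    "build_master_operator",
    "fpt_distribution",
    "log_time_density",
    "mfpt",
    "peak_times",
    "run_endpoint_analysis",
]


@dataclass(frozen=True)
class EndpointSets:
    """Disjoint product (A) and reactant (B) minima sets, 0-based ids."""

    A: frozenset
    B: frozenset

    def __post_init__(self):
        object.__setattr__(self, "A", frozenset(int(i) for i in self.A))
        object.__setattr__(self, "B", frozenset(int(i) for i in self.B))
        if not self.A or not self.B:
            raise ValueError("endpoint sets A and B must be non-empty")
        if self.A & self.B:
            raise ValueError(f"endpoint sets overlap: {sorted(self.A & self.B)}")

    def validate(self, n_states: int) -> None:
        bad = [i for i in self.A | self.B if not 0 <= i < n_states]
        if bad:
            raise ValueError(f"endpoint ids out of range: {sorted(bad)}")

    def intervening(self, n_states: int) -> list[int]:
        return [i for i in range(n_states) if i not in self.A and i not in self.B]


@dataclass
class MasterOperator:
    """Generator M over the surviving states (ordered I then B), A absorbing."""

    matrix: np.ndarray
    states: np.ndarray            # network ids in row/column order
    eq_weights: np.ndarray        # equilibrium weights of those states
    target: frozenset
    reactants: frozenset
    detailed_balance: bool

    @property
    def n(self) -> int:
        return self.states.size


@dataclass
class FPTDistribution:
    """Exponential-mixture FPT distribution: p(t) = sum nu_l A_l exp(-nu_l t)."""

    eigenvalues: np.ndarray       # nu_l, ps^-1, ascending
    amplitudes: np.ndarray        # A_l, sum to 1 for total absorption
    initial: str = ""

    def __post_init__(self):
        order = np.argsort(self.eigenvalues)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)[order]
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)[order]

    def pdf(self, t: np.ndarray) -> np.ndarray:
        """p(t) on a time grid (ps)."""
        t = np.asarray(t, dtype=float)
        return np.einsum("l,lt->t", self.eigenvalues * self.amplitudes,
                         np.exp(-np.outer(self.eigenvalues, t)))

    def survival(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.einsum("l,lt->t", self.amplitudes,
                         np.exp(-np.outer(self.eigenvalues, t)))


# ---------------------------------------------------------------------------
# endpoint files
# ---------------------------------------------------------------------------

def read_min_file(path: str | Path, n_states: int | None = None) -> list[int]:
    """Parse a min.A / min.B file: count first, then 1-based ids; returns 0-based."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines()]
    stripped = [(no, ln.strip()) for no, ln in enumerate(lines, start=1) if ln.strip()]
    if not stripped:
        raise ValueError(f"{path}: empty endpoint file")
    try:
        count = int(stripped[0][1].split()[0])
    except ValueError as exc:
        raise ValueError(f"{path} line {stripped[0][0]}: expected a count") from exc
    ids: list[int] = []
    for no, ln in stripped[1:]:
        for tok in ln.split():
            try:
                mid = int(tok)
            except ValueError as exc:
                raise ValueError(f"{path} line {no}: not a minimum id: {tok!r}") from exc
            if n_states is not None and not 1 <= mid <= n_states:
                raise ValueError(
                    f"{path} line {no}: minimum id {mid} out of range 1..{n_states}"
                )
            ids.append(mid - 1)
    if len(ids) != count:
        raise ValueError(f"{path}: header says {count} minima, found {len(ids)}")
    return ids


def write_min_file(ids, path: str | Path) -> None:
    """Write 0-based ids as a PATHSAMPLE endpoint file (1-based)."""
    ids = list(ids)
    with open(path, "w") as fh:
        fh.write(f"{len(ids)}\n")
        for i in ids:
            fh.write(f"{int(i) + 1}\n")


# ---------------------------------------------------------------------------
# operator assembly and spectral solution
# ---------------------------------------------------------------------------

def build_master_operator(net: KineticNetwork, ep: EndpointSets) -> MasterOperator:
    """Assemble M over I u B with the product set A absorbing.

    Off-diagonal M[a, b] = k(b -> a); diagonal entries carry minus the total
    escape rate of each state, including flux into A.  Raises when some
    surviving state cannot reach A (its first passage time would diverge).
    """
    ep.validate(net.n_states)
    surviving = ep.intervening(net.n_states) + sorted(ep.B)
    _check_reachability(net.rates, surviving, ep.A)
    idx = {s: i for i, s in enumerate(surviving)}
    n = len(surviving)
    m = np.zeros((n, n))
    for a in surviving:
        ia = idx[a]
        m[ia, ia] = -net.rates[a].sum()
        for b in surviving:
            if a != b and net.rates[b, a] > 0:
                m[idx[a], idx[b]] = net.rates[b, a]
    if net.probability is not None:
        pi = np.asarray([net.probability[s] for s in surviving], dtype=float)
    else:
        pi = np.exp(-np.asarray([net.free_energy[s] for s in surviving]))
    pi = pi / pi.sum()
    db = _detailed_balance_holds(net.rates, surviving, pi)
    return MasterOperator(m, np.asarray(surviving, dtype=np.intp), pi,
                          frozenset(ep.A), frozenset(ep.B), db)


def _check_reachability(rates: np.ndarray, surviving, target) -> None:
    target = set(target)
    reached = set(target)
    frontier = set(target)
    surviving_set = set(surviving)
    while frontier:
        nxt = set()
        for s in surviving_set - reached:
            if any(rates[s, t] > 0 for t in reached):
                nxt.add(s)
        if not nxt:
            break
        reached |= nxt
        frontier = nxt
    stranded = sorted(surviving_set - reached)
    if stranded:
        raise ValueError(
            f"states {stranded} cannot reach the absorbing set {sorted(target)}; "
            "their first passage time is undefined"
        )


def _detailed_balance_holds(rates, surviving, pi, rtol=1e-8) -> bool:
    scale = 0.0
    worst = 0.0
    for i, a in enumerate(surviving):
        for j, b in enumerate(surviving):
            if j <= i:
                continue
            flux_ab = pi[i] * rates[a, b]
            flux_ba = pi[j] * rates[b, a]
            scale = max(scale, flux_ab, flux_ba)
            worst = max(worst, abs(flux_ab - flux_ba))
    return scale == 0.0 or worst <= rtol * scale


def fpt_distribution(op: MasterOperator, initial="local_equilibrium",
                     ) -> FPTDistribution:
    """Spectral FPT distribution for a given initial distribution.

    ``initial`` may be ``"local_equilibrium"`` (equilibrium weights restricted
    to B -- all non-intervening surviving states), ``"uniform"`` (uniform on
    those states), a single network state id, or an explicit probability
    vector over the operator's state ordering.

    When detailed balance holds, -M is symmetrized by the square-root
    equilibrium-weight similarity transform and solved with a symmetric
    eigensolver; otherwise a general dense solver is used and every
    eigenpair's residual is checked.
    """
    p0, label = _initial_vector(op, initial)
    neg_m = -op.matrix
    if op.detailed_balance:
        sqrt_pi = np.sqrt(op.eq_weights)
        sym = neg_m * (sqrt_pi[None, :] / sqrt_pi[:, None])
        sym = 0.5 * (sym + sym.T)
        nu, u = scipy.linalg.eigh(sym)
        # right eigenvectors of -M and the dual basis
        v = u * sqrt_pi[:, None]
        w = u / sqrt_pi[:, None]
        amplitudes = v.sum(axis=0) * (w.T @ p0)
    else:
        nu_c, v = scipy.linalg.eig(neg_m)
        if np.abs(nu_c.imag).max(initial=0.0) > 1e-9 * max(1.0, np.abs(nu_c.real).max()):
            raise ValueError(
                "complex eigenvalues encountered for a non-detailed-balance "
                "operator; the exponential-mixture form does not apply"
            )
        nu = nu_c.real
        resid = np.linalg.norm(neg_m @ v - v * nu_c[None, :], axis=0)
        if resid.max() > 1e-9 * max(1.0, np.abs(nu).max()):
            raise np.linalg.LinAlgError(
                "eigendecomposition residual too large (near-defective matrix); "
                "consider merging nearly degenerate states"
            )
        w = np.linalg.inv(v)
        amplitudes = (v.sum(axis=0) * (w @ p0)).real
    if nu.min() <= 0:
        raise ValueError(
            "non-positive eigenvalue of -M: the absorbing set is not reached "
            "from every surviving state"
        )
    return FPTDistribution(nu, amplitudes, label)


def _initial_vector(op: MasterOperator, initial):
    n = op.n
    if isinstance(initial, str):
        # reactant states = surviving states tagged as B (everything that is
        # not intervening); here: states with any weight assigned by caller.
        if initial not in ("local_equilibrium", "uniform"):
            raise ValueError(f"unknown initial condition {initial!r}")
        b_mask = np.asarray([s in op.reactants for s in op.states])
        if not b_mask.any():
            b_mask = np.ones(n, dtype=bool)
        p0 = np.zeros(n)
        if initial == "local_equilibrium":
            p0[b_mask] = op.eq_weights[b_mask]
        else:
            p0[b_mask] = 1.0
        p0 /= p0.sum()
        return p0, initial
    if np.isscalar(initial):
        state = int(initial)
        where = np.flatnonzero(op.states == state)
        if where.size == 0:
            raise ValueError(f"start state {state} is not a surviving state")
        p0 = np.zeros(n)
        p0[where[0]] = 1.0
        return p0, f"state:{state}"
    p0 = np.asarray(initial, dtype=float)
    if p0.shape != (n,):
        raise ValueError(f"initial vector must have shape ({n},)")
    if not np.isclose(p0.sum(), 1.0):
        raise ValueError("initial distribution must sum to 1")
    return p0, "custom"


def mfpt(d: FPTDistribution) -> float:
    """Mean first-passage time sum_l A_l / nu_l, in ps."""
    return float(np.sum(d.amplitudes / d.eigenvalues))


def log_time_density(d: FPTDistribution, y_grid: np.ndarray) -> np.ndarray:
    """P(y) with y = ln(t / 1 ps): sum_l nu_l exp(y - nu_l e^y) A_l."""
    y = np.asarray(y_grid, dtype=float)
    with np.errstate(over="ignore", under="ignore"):
        expo = y[None, :] - d.eigenvalues[:, None] * np.exp(y)[None, :]
        terms = d.eigenvalues[:, None] * np.exp(expo)
    return np.einsum("l,lt->t", d.amplitudes, terms)


def default_y_grid(d: FPTDistribution, margin: float = 10.0, n: int = 2001,
                   ) -> np.ndarray:
    lo = -np.log(d.eigenvalues.max()) - margin
    hi = -np.log(d.eigenvalues.min()) + margin
    return np.linspace(lo, hi, n)


def peak_times(d: FPTDistribution, margin: float = 5.0, n_grid: int = 8001,
               ) -> list[tuple[float, float]]:
    """Local maxima of P(y), refined by bisection on dP/dy.

    Returns (y*, P(y*)) pairs with y in ln(ps); exp(y*) is the most probable
    transition time in ps.
    """
    y = np.linspace(-np.log(d.eigenvalues.max()) - margin,
                    -np.log(d.eigenvalues.min()) + margin, n_grid)
    p = log_time_density(d, y)

    def dp(yv):
        with np.errstate(over="ignore", under="ignore"):
            e = np.exp(yv)
            terms = d.amplitudes * d.eigenvalues * np.exp(yv - d.eigenvalues * e) \
                * (1.0 - d.eigenvalues * e)
        return terms.sum()

    peaks = []
    for i in range(1, y.size - 1):
        if p[i] > p[i - 1] and p[i] >= p[i + 1]:
            lo, hi = y[i - 1], y[i + 1]
            if dp(lo) > 0 > dp(hi):
                for _ in range(60):
                    mid = 0.5 * (lo + hi)
                    if dp(mid) > 0:
                        lo = mid
                    else:
                        hi = mid
            y_star = 0.5 * (lo + hi)
            peaks.append((float(y_star), float(log_time_density(d, np.array([y_star]))[0])))
    return peaks


# ---------------------------------------------------------------------------
# PATHSAMPLE-style endpoint analysis
# ---------------------------------------------------------------------------

def _write_lnpdf(path: Path, d: FPTDistribution) -> None:
    y = default_y_grid(d)
    p = log_time_density(d, y)
    with open(path, "w") as fh:
        for yi, pi in zip(y, p):
            fh.write(f"{yi:18.10f} {pi:20.12e}\n")


def _write_peaks(path: Path, d: FPTDistribution) -> None:
    with open(path, "w") as fh:
        fh.write("#        ln(t/ps)                 P(y)                 t/ps\n")
        for y_star, p_star in peak_times(d):
            fh.write(f"{y_star:18.10f} {p_star:20.12e} {np.exp(y_star):20.10f}\n")


def _set_to_set(net: KineticNetwork, targets, sources, initial: str):
    ep = EndpointSets(frozenset(targets), frozenset(sources))
    op = build_master_operator(net, ep)
    return fpt_distribution(op, initial), op


def run_endpoint_analysis(net: KineticNetwork, min_a_path: str | Path,
                          min_b_path: str | Path, out_dir: str | Path = ".",
                          waitpdfprint: bool = False,
                          initial: str = "local_equilibrium") -> dict:
    """Compute FPT distributions between the endpoint sets of min.A / min.B.

    Writes ``waitlnpdfAB`` (B -> A) and ``waitlnpdfBA`` (A -> B); with
    ``waitpdfprint`` also per-start-state ``waitlnpdfA.ID`` / ``peaksA.ID``
    (target A) and ``waitlnpdfB.ID`` / ``peaksB.ID`` (target B), where ID is
    the 1-based id of the single start minimum.  Returns the distributions
    and MFPTs keyed by direction.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    a_ids = read_min_file(min_a_path, net.n_states)
    b_ids = read_min_file(min_b_path, net.n_states)

    d_ab, _ = _set_to_set(net, a_ids, b_ids, initial)   # B -> A
    d_ba, _ = _set_to_set(net, b_ids, a_ids, initial)   # A -> B
    _write_lnpdf(out_dir / "waitlnpdfAB", d_ab)
    _write_lnpdf(out_dir / "waitlnpdfBA", d_ba)
    results = {
        "AB": {"distribution": d_ab, "mfpt_ps": mfpt(d_ab)},
        "BA": {"distribution": d_ba, "mfpt_ps": mfpt(d_ba)},
    }
    if waitpdfprint:
        for label, targets in (("A", a_ids), ("B", b_ids)):
            target_set = set(targets)
            for start in range(net.n_states):
                if start in target_set:
                    continue
                ep = EndpointSets(frozenset(targets), frozenset([start]))
                op = build_master_operator(net, ep)
                d = fpt_distribution(op, start)
                _write_lnpdf(out_dir / f"waitlnpdf{label}.{start + 1}", d)
                _write_peaks(out_dir / f"peaks{label}.{start + 1}", d)
    return results
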