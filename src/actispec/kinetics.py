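"""Decay-chain kinetics: closed-form Bateman solution and equilibrium times.

The chain abundances obey the linear system dN_i/dt = -lambda_i N_i +
sum_p b_{p->i} lambda_p N_p.  With the nuclides in parent-before-child
order the system matrix is triangular, so each abundance is a sum of
exponentials N_i(t) = sum_j c_ij exp(-lambda_j t); the coefficients
follow the classic Bateman recursion generalized to branching.  The
closed form is exact at any t, which matters here because At-217
(32 ms) and Po-213 (4 us) make the equivalent ODE system extremely
stiff.

Activities are A_i = lambda_i N_i, reported in kBq.  The standard
initial condition is a pure parent sample: A_parent(0) = A0, all
daughters zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nuclides import DecayChain

#: decay constants closer than this (relative) are jittered apart so the
#: distinct-eigenvalue Bateman form remains valid (degenerate-limit handling)
_DEGENERACY_RTOL = 1e-10


@dataclass
class ActivitySeries:
    """Chain activities on a time grid.

    ``activities[name]`` is the activity of that nuclide in kBq at each
    grid time (seconds).
    """

    times_s: np.ndarray
    activities: dict[str, np.ndarray]
    initial_activity_kbq: float

    def __getitem__(self, name: str) -> np.ndarray:
        return self.activities[name]

    def ratio(self, daughter: str, parent: str) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.activities[daughter] / self.activities[parent]

    def to_frame(self):
        """Tidy (time_s, nuclide, activity_kbq) table."""
        import pandas as pd

        frames = [
            pd.DataFrame(
                {"time_s": self.times_s, "nuclide": name, "activity_kbq": act}
            )
            for name, act in self.activities.items()
        ]
        return pd.concat(frames, ignore_index=True)


def _bateman_coefficients(chain: DecayChain) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient matrix c[i, j] and the (jittered) decay constants.

    N_i(t) = sum_j c[i, j] * exp(-lam[j] * t) for a unit initial parent
    abundance (N_0(0) = 1, daughters 0).
    """
    n = len(chain)
    lam = np.array([nuc.decay_constant for nuc in chain], dtype=float)
    # regularize degenerate eigenvalues (none occur in the bundled chain)
    for i in range(n):
        for j in range(i):
            if lam[j] > 0 and abs(lam[i] - lam[j]) <= _DEGENERACY_RTOL * lam[j]:
                lam[i] *= 1.0 + 1e-9
    index = {name: k for k, name in enumerate(chain.names)}
    feeds: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for i, nuc in enumerate(chain):
        for child, frac in nuc.decays_to:
            feeds[index[child]].append((i, frac))
    c = np.zeros((n, n))
    c[0, 0] = 1.0
    for i in range(1, n):
        for j in range(i):
            inflow = sum(frac * lam[p] * c[p, j] for p, frac in feeds[i])
            if inflow:
                c[i, j] = inflow / (lam[i] - lam[j])
        c[i, i] = -c[i, : i].sum()  # N_i(0) = 0
    return c, lam


def solve_chain(
    chain: DecayChain, a0_kbq: float, times_s: np.ndarray
) -> ActivitySeries:
    """Closed-form chain activities for a pure-parent initial sample.

    Parameters
    ----------
    a0_kbq : initial parent activity (daughters start at zero).
    times_s : sorted, nonnegative time grid in seconds.
    """
    times_s = np.asarray(times_s, dtype=float)
    if a0_kbq < 0:
        raise ValueError("initial activity must be nonnegative")
    if times_s.ndim != 1 or (len(times_s) > 1 and np.any(np.diff(times_s) <= 0)):
        raise ValueError("times must be a strictly increasing 1-D grid")
    if len(times_s) and times_s[0] < 0:
        raise ValueError("times must be nonnegative")

    c, lam = _bateman_coefficients(chain)
    lam_parent = chain.parent.decay_constant
    n_parent0 = a0_kbq * 1e3 / lam_parent  # atoms, from kBq
    decays = np.exp(-np.outer(lam, times_s))  # (n, t)
    atoms = n_parent0 * (c @ decays)
    activities = {
        name: lam[i] * atoms[i] / 1e3  # back to kBq
        for i, name in enumerate(chain.names)
    }
    return ActivitySeries(times_s, activities, a0_kbq)


def asymptotic_ratio(chain: DecayChain, daughter: str, parent: str | None = None) -> float:
    """Limit of A_daughter / A_parent as t -> infinity (secular-equilibrium ratio).

    At late times every member decays with the parent's (smallest) decay
    constant, so the ratio is fixed by the slowest Bateman mode.
    """
    parent = parent or chain.parent.name
    c, lam = _bateman_coefficients(chain)
    i_d = chain.names.index(daughter)
    i_p = chain.names.index(parent)
    j = int(np.argmin(np.where(lam > 0, lam, np.inf)))
    if c[i_d, j] == 0 or c[i_p, j] == 0:
        raise ValueError(f"no common asymptotic mode for {daughter}/{parent}")
    return float(lam[i_d] * c[i_d, j] / (lam[i_p] * c[i_p, j]))


def time_to_equilibrium(
    chain: DecayChain,
    a0_kbq: float,
    nuclide: str,
    tolerance: float,
    *,
    reference: str = "asymptote",
    dt_s: float = 60.0,
    horizon_s: float = 86400.0,
) -> float:
    """First grid time after which the daughter/parent activity ratio stays converged.

    ``reference="asymptote"`` tests |r(t)/r_inf - 1| <= tolerance against
    the exact asymptotic ratio; ``reference="unity"`` tests
    |r(t) - 1| <= tolerance, i.e. the daughter tracking the parent to
    within the tolerance.  The grid step is 1 minute by default.  The
    condition must hold at every later grid point out to ``horizon_s``;
    if it never does, the horizon is too short and an error is raised.
    """
    if not 0 < tolerance < 1:
        raise ValueError("tolerance must be in (0, 1)")
    if nuclide == chain.parent.name:
        raise ValueError("nuclide must be a daughter of the chain parent")
    times = np.arange(0.0, horizon_s + dt_s, dt_s)
    series = solve_chain(chain, a0_kbq, times)
    r = series.ratio(nuclide, chain.parent.name)
    if reference == "asymptote":
        target = asymptotic_ratio(chain, nuclide)
        dev = np.abs(r / target - 1.0)
    elif reference == "unity":
        dev = np.abs(r - 1.0)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    ok = dev <= tolerance
    # last index at which the criterion fails; converged ever after
    bad = np.nonzero(~ok)[0]
    if len(bad) == len(times) or (len(bad) and bad[-1] == len(times) - 1):
        raise RuntimeError(
            f"{nuclide} does not converge to within {tolerance} by "
            f"{horizon_s} s: horizon too short"
        )
    first = times[bad[-1] + 1] if len(bad) else times[0]
    return float(first)
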