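"""Independent oracles used by the test suite.

These deliberately avoid the package's ODE-assembly/integration path:
steady states are computed from closed forms (two-node quadratic, cubic
normal form) or from a sequential steady-state chain solve (the full
biochemical network), so that agreement with the simulated/continued
results is a genuine two-route check.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

HGF = 1.0


def two_node_steady_state(ksynthA, kdegA, ksynthB, kdegB, kiA, kiB):
    """Unique nonnegative fixed point of the mass-action two-node motif.

    Eliminating A = ksynthA / (kdegA + kiB*B) from dB/dt = 0 gives a
    quadratic in B with a positive and a negative root (product of roots
    < 0), hence exactly one admissible steady state.
    """
    # (ksynthB - kdegB*B)(kdegA + kiB*B) - kiA*ksynthA*B = 0
    a = -kdegB * kiB
    b = ksynthB * kiB - kdegB * kdegA - kiA * ksynthA
    c = ksynthB * kdegA
    if a == 0:  # kiB = 0: linear in B
        B = -c / b if b != 0 else np.nan
    else:
        # cancellation-free quadratic roots (Kahan's form)
        disc = b * b - 4 * a * c
        q = -0.5 * (b + np.copysign(np.sqrt(disc), b))
        r1, r2 = q / a, (c / q if q != 0 else np.inf)
        B = max(r1, r2) if max(r1, r2) >= 0 else min(r1, r2)
    A = ksynthA / (kdegA + kiB * B)
    return np.array([A, B])


CUBIC_FOLD = 2.0 / (3.0 * np.sqrt(3.0))  # folds of dx/dt = r + x - x^3


def cubic_equilibria(r):
    """Real roots of r + x - x^3 = 0, ascending."""
    roots = np.roots([-1.0, 0.0, 1.0, r])
    return np.sort(roots[np.abs(roots.imag) < 1e-9].real)


def chain_steady_states(params: dict, tension: bool,
                        lo=1e-4, hi=1e7, n=3000) -> list[dict]:
    """All fixed points of the reconstructed network via 1-D root finding.

    Given the active-RhoA level R, every downstream species' steady state
    follows in closed form (NO from a quadratic, cGMP from a monotone 1-D
    equation); the RhoA balance then yields a self-consistency residual
    g(R) whose roots are the network's fixed points.
    """
    def chain(R):
        p = params
        ROCK = p["k12"] * R / p["kdeg4"]
        Akt = (p["k6"] * HGF + p["kb1"]) / (p["kdeg3"] + p["ki1"] * ROCK)
        mRNA = p["k7"] / (p["kdeg5"] + p["ki2"] * R)
        drain = p["k9"] * Akt * p["kdeg7"] / (p["k10"] + p["kdeg7"])
        E = p["k8"] * mRNA / (p["kdeg6"] + drain)
        Ep = p["k9"] * Akt * E / (p["k10"] + p["kdeg7"])
        S = p["k11"] * Ep + p["k13"] * E
        NO = (-p["kdeg8"] + np.sqrt(p["kdeg8"] ** 2 + 8 * p["kox"] * S)) / (
            4 * p["kox"])

        def pkg_of(c):
            cn = c ** p["ncgmp"]
            return (p["k15"] / p["kdeg10"]) * cn / (p["Kmcgmp"] ** p["ncgmp"] + cn)

        def cres(c):
            return p["k14"] * NO - p["kdeg9"] * c - p["kpde"] * pkg_of(c) * c

        c = brentq(cres, 0.0, p["k14"] * NO / p["kdeg9"] + 1e-12,
                   xtol=1e-14, rtol=1e-13)
        PKG = pkg_of(c)
        a = p["k2"] * HGF + p["kb2"]
        T = 0.0
        if tension:
            T = p["k16"] * ROCK / (p["kdeg11"] + p["k18"] * c)
            a = a + p["k17"] * T
        kphos = p["k4"] * PKG
        conv = (p["k3"] + p["k5"] * kphos / (p["k5"] + p["kdeg2"])) / (
            p["k3"] + kphos)
        G = p["k1"] / (p["kdeg1"] + a * (1.0 - conv))
        R_out = a * G / (p["k3"] + kphos)
        P = kphos * R_out / (p["k5"] + p["kdeg2"])
        return dict(R_out=R_out, G=G, P=P, ROCK=ROCK, Akt=Akt, mRNA=mRNA,
                    E=E, Ep=Ep, NO=NO, cGMP=c, PKG=PKG, T=T)

    Rs = np.geomspace(lo, hi, n)
    gs = np.array([chain(R)["R_out"] - R for R in Rs])
    out = []
    sg = np.sign(gs)
    for i in np.nonzero(sg[:-1] != sg[1:])[0]:
        R = brentq(lambda R: chain(R)["R_out"] - R, Rs[i], Rs[i + 1],
                   xtol=1e-12, rtol=1e-12)
        d = chain(R)
        d["R"] = R
        out.append(d)
    return out


def chain_state_vector(d: dict, tension: bool) -> np.ndarray:
    """Full state vector in model species order from one chain solution."""
    v = [d["G"], d["R"], d["P"], d["ROCK"], d["Akt"], d["mRNA"], d["E"],
         d["Ep"], d["NO"], d["cGMP"], d["PKG"]]
    if tension:
        v.append(d["T"])
    return np.array(v)


def toy_switch_fixed_points(k, K, d):
    """Nonzero fixed points of dx/dt = k*x^2/(K^2+x^2) - d*x.

    x = 0 is always a fixed point; the nonzero pair solves
    d*x^2 - k*x + d*K^2 = 0 and exists iff k >= 2*K*d.
    """
    disc = k * k - 4 * d * d * K * K
    if disc < 0:
        return []
    return sorted([(k - np.sqrt(disc)) / (2 * d), (k + np.sqrt(disc)) / (2 * d)])
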