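"""Pairwise maximum-likelihood codon divergence under a GY-style model.

Two-sequence codon model with F3x4 codon frequencies and free parameters
(t, kappa, omega): the instantaneous rate between sense codons differing at
one position is pi_j * kappa^[transition] * omega^[nonsynonymous], scaled so
t is measured in expected substitutions per codon.  dS and dN are derived
from the fitted parameters via the model's expected proportions of
synonymous and nonsynonymous substitutions and the corresponding
mutational-opportunity site counts.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.optimize import minimize

from sagkit.codon import SENSE_CODONS, comparable_codon_pairs, is_synonymous

_PURINES = {"A", "G"}


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES)


@lru_cache(maxsize=1)
def _neighbor_structure():
    """Static index arrays over single-position sense-codon neighbours."""
    n = len(SENSE_CODONS)
    I, J, TS, SYN, POS, TO = [], [], [], [], [], []
    base_index = {"T": 0, "C": 1, "A": 2, "G": 3}
    for i, c1 in enumerate(SENSE_CODONS):
        for j, c2 in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [k for k in range(3) if c1[k] != c2[k]]
            if len(diff) != 1:
                continue
            k = diff[0]
            I.append(i)
            J.append(j)
            TS.append(_is_transition(c1[k], c2[k]))
            SYN.append(is_synonymous(c1, c2))
            POS.append(k)
            TO.append(base_index[c2[k]])
    return (
        n,
        np.array(I),
        np.array(J),
        np.array(TS, dtype=bool),
        np.array(SYN, dtype=bool),
        np.array(POS),
        np.array(TO),
    )


def f3x4_frequencies(cds_pair) -> np.ndarray:
    """F3x4 equilibrium codon frequencies from the two (ungapped) CDS."""
    counts = np.full((3, 4), 1e-6)  # position x TCAG, small pseudocount
    base_index = {"T": 0, "C": 1, "A": 2, "G": 3}
    for cds in cds_pair:
        for k, ch in enumerate(cds):
            idx = base_index.get(ch)
            if idx is not None:
                counts[k % 3, idx] += 1
    counts /= counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            counts[0, base_index[c[0]]]
            * counts[1, base_index[c[1]]]
            * counts[2, base_index[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


def _rate_matrix(pi: np.ndarray, kappa: float, omega: float):
    """Scaled GY rate matrix; returns (Q, fraction of flux synonymous)."""
    n, I, J, TS, SYN, _, _ = _neighbor_structure()
    rates = pi[J] * np.where(TS, kappa, 1.0) * np.where(SYN, 1.0, omega)
    Q = np.zeros((n, n))
    Q[I, J] = rates
    Q[np.diag_indices(n)] = -Q.sum(axis=1)
    total_flux = float(np.sum(pi[I] * rates))
    syn_flux = float(np.sum(pi[I[SYN]] * rates[SYN]))
    Q /= total_flux  # one expected substitution per codon per unit t
    rho_s = syn_flux / total_flux
    return Q, rho_s


def _transition_probabilities(Q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Qt) via symmetric eigendecomposition (Q is reversible)."""
    d = np.sqrt(pi)
    B = (Q * d[:, None]) / d[None, :]
    B = 0.5 * (B + B.T)  # symmetrize against round-off
    w, V = np.linalg.eigh(B)
    P = (V * np.exp(w * t)) @ V.T
    P = P / d[:, None] * d[None, :]
    return np.clip(P, 1e-300, None)


def _site_fractions(pi: np.ndarray, kappa: float):
    """Synonymous mutational-opportunity fraction at omega = 1."""
    _, rho_s1 = _rate_matrix(pi, kappa, 1.0)
    return rho_s1


def ml_pairwise(cds1: str, cds2: str, min_codons: int = 10):
    """Fit (t, kappa, omega) to one aligned CDS pair; return divergence dict.

    Returns keys ``dS, dN, omega, t, kappa, loglik``.  Identical sequences
    (or no comparable codons with any difference) return dS = dN = 0 exactly.
    Raises ``ValueError`` with fewer than ``min_codons`` comparable codons.
    """
    i1, i2 = comparable_codon_pairs(cds1, cds2)
    if len(i1) < min_codons:
        raise ValueError(f"only {len(i1)} comparable codons (<{min_codons})")
    if np.all(i1 == i2):
        return {"dS": 0.0, "dN": 0.0, "omega": 0.0, "t": 0.0, "kappa": 1.0, "loglik": 0.0}

    n = len(SENSE_CODONS)
    counts = np.zeros((n, n))
    np.add.at(counts, (i1, i2), 1.0)
    nonzero = counts > 0
    ci, cj = np.nonzero(nonzero)
    cn = counts[ci, cj]

    degapped1 = "".join(SENSE_CODONS[k] for k in i1)
    degapped2 = "".join(SENSE_CODONS[k] for k in i2)
    pi = f3x4_frequencies((degapped1, degapped2))
    log_pi = np.log(pi)

    def negloglik(x):
        t, kappa, omega = np.exp(x)
        Q, _ = _rate_matrix(pi, kappa, omega)
        P = _transition_probabilities(Q, pi, t)
        return -float(np.sum(cn * (log_pi[ci] + np.log(P[ci, cj]))))

    bounds = [(np.log(1e-4), np.log(50.0)), (np.log(0.05), np.log(50.0)),
              (np.log(1e-4), np.log(20.0))]
    best = None
    for t0 in (0.1, 1.0, 3.0):
        x0 = np.log([t0, 2.0, 0.4])
        res = minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    t, kappa, omega = np.exp(best.x)
    _, rho_s = _rate_matrix(pi, kappa, omega)
    rho_s1 = _site_fractions(pi, kappa)
    s_sites = 3.0 * rho_s1  # synonymous sites per codon
    dS = t * rho_s / s_sites if s_sites > 0 else 0.0
    dN = t * (1.0 - rho_s) / (3.0 - s_sites) if s_sites < 3.0 else 0.0
    return {
        "dS": float(dS),
        "dN": float(dN),
        "omega": float(omega),
        "t": float(t),
        "kappa": float(kappa),
        "loglik": -float(best.fun),
    }
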