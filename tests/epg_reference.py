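"""Brute-force extended-phase-graph reference implementation.

Deliberately naive and independent of the package's optimized recursion:
complex-valued configuration states, explicit per-state 3x3 rotation
matrices applied in a Python loop, and index-by-index dephasing shifts.
Used as the oracle for equivalence tests.
"""

from __future__ import annotations

import numpy as np


def epg_echo_amplitudes_reference(
    t2: float,
    n_echoes: int,
    echo_spacing: float,
    refocus_deg: float,
    t1: float = 1000.0,
) -> np.ndarray:
    """Echo amplitudes of a CPMG train by the textbook complex EPG.

    States: F+_k, F-_k (= conj of the order -k transverse state), Z_k for
    k = 0..K with K = 2 * n_echoes. Excitation puts all magnetization into
    F+_0. Each echo period is: relax tau, dephase +1, rotate by alpha about
    the x axis (explicit 3x3 complex matrix per k), relax tau, dephase +1;
    the echo is the k = 0 transverse state.
    """
    k_max = 2 * n_echoes
    fp = np.zeros(k_max + 2, dtype=complex)
    fm = np.zeros(k_max + 2, dtype=complex)
    z = np.zeros(k_max + 2, dtype=complex)
    fp[0] = 1.0

    tau = echo_spacing / 2.0
    e2 = np.exp(-tau / t2)
    e1 = np.exp(-tau / t1)
    a = np.deg2rad(refocus_deg)
    rot = np.array(
        [
            [np.cos(a / 2) ** 2, np.sin(a / 2) ** 2, -1j * np.sin(a)],
            [np.sin(a / 2) ** 2, np.cos(a / 2) ** 2, 1j * np.sin(a)],
            [-0.5j * np.sin(a), 0.5j * np.sin(a), np.cos(a)],
        ],
        dtype=complex,
    )

    def relax() -> None:
        for k in range(k_max + 2):
            fp[k] *= e2
            fm[k] *= e2
            z[k] *= e1

    def dephase() -> None:
        # F(k) -> F(k+1) for every order k in -K..K.
        for k in range(k_max, 0, -1):
            fp[k] = fp[k - 1]
        fp[0] = np.conj(fm[1])  # order -1 moves up to order 0
        for k in range(0, k_max + 1):
            fm[k] = fm[k + 1]
        fm[k_max + 1] = 0.0

    def rotate() -> None:
        for k in range(k_max + 1):
            vec = np.array([fp[k], fm[k], z[k]], dtype=complex)
            fp[k], fm[k], z[k] = rot @ vec
        # Consistency at order 0: F-_0 is the conjugate of F+_0.
        fm[0] = np.conj(fp[0])

    echoes = np.empty(n_echoes)
    for _ in range(n_echoes):
        relax()
        dephase()
        rotate()
        relax()
        dephase()
        echoes[_] = np.abs(fp[0])
    return echoes
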