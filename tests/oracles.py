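"""Independent reference implementations used only as test oracles.

These deliberately take different routes than the package:

- ``beam_first_eigenfrequency``: a finite-difference discretization of the
  Euler-Bernoulli cantilever eigenproblem (smallest eigenfrequency), checking
  the closed-form mode-constant formula.
- ``mason_transfer``: the piezo plate as a three-port impedance matrix (the
  Mason constitutive form) with matching layers as ABCD two-ports, solved as
  a dense linear system per frequency — checking the KLM circuit.
"""

from __future__ import annotations

import numpy as np

EPS0 = 8.8541878128e-12


def beam_first_eigenfrequency(
    youngs_modulus: float,
    density: float,
    radius: float,
    length: float,
    n: int = 800,
) -> float:
    """Smallest flexural eigenfrequency (Hz) of a clamped-free circular beam.

    Discretizes EI w'''' = rho A omega^2 w with second-order differences,
    clamped (w = w' = 0) at x=0 and free (w'' = w''' = 0) at x=L, and returns
    the smallest eigenvalue's frequency.
    """
    E, rho, R, L = youngs_modulus, density, radius, length
    I = np.pi * R**4 / 4.0
    A = np.pi * R**2
    h = L / n
    m = np.zeros((n, n))

    def add(row, col, val):
        if 0 <= col < n:
            m[row, col] += val

    # unknowns w_1..w_n -> columns 0..n-1; w_0 = 0, ghost w_{-1} = w_1
    for i in range(1, n + 1):
        row = i - 1
        stencil = {i - 2: 1.0, i - 1: -4.0, i: 6.0, i + 1: -4.0, i + 2: 1.0}
        # clamped end: w_0 = 0 (drop), w_{-1} = w_1
        if i - 2 == -1:
            stencil[1] = stencil.get(1, 0.0) + stencil.pop(-1)
        stencil.pop(0, None)
        # free end ghosts: w_{n+1} = 2 w_n - w_{n-1};
        # w_{n+2} = 2 w_{n+1} - 2 w_{n-1} + w_{n-2}
        if n + 1 in stencil:
            c = stencil.pop(n + 1)
            stencil[n] = stencil.get(n, 0.0) + 2.0 * c
            stencil[n - 1] = stencil.get(n - 1, 0.0) - c
        if n + 2 in stencil:
            c = stencil.pop(n + 2)
            # expand w_{n+2}, then the embedded w_{n+1} again
            stencil[n] = stencil.get(n, 0.0) + 4.0 * c
            stencil[n - 1] = stencil.get(n - 1, 0.0) - 2.0 * c - 2.0 * c
            stencil[n - 2] = stencil.get(n - 2, 0.0) + c
        for col_node, val in stencil.items():
            add(row, col_node - 1, val)

    eigvals = np.linalg.eigvals(m / h**4)
    eigvals = np.real(eigvals[np.abs(np.imag(eigvals)) < 1e-6 * np.abs(eigvals).max()])
    lam = np.min(eigvals[eigvals > 0])
    omega = np.sqrt(lam * E * I / (rho * A))
    return omega / (2.0 * np.pi)


def mason_transfer(
    freqs,
    thickness: float,
    velocity: float,
    density: float,
    kt: float,
    eps_r: float,
    area: float,
    front_layers=(),
    z_front: float = 1.48e6,
    z_back: float = 3.05e6,
    source_impedance: float = 50.0,
):
    """Transmit and receive transfer of a loaded piezo plate, Mason route.

    ``front_layers``: sequence of (velocity, density, thickness) from the
    piezo outward.  ``z_front``/``z_back`` are the face load impedances in
    Rayl.  Returns (Ht, Hr): force-into-front-load per source volt, and
    receiver voltage per unit incident force.
    """
    w = 2.0 * np.pi * np.asarray(freqs, dtype=float)
    zc = density * velocity * area
    c0 = eps_r * EPS0 * area / thickness
    h_const = np.sqrt(kt**2 * density * velocity**2 * area / (c0 * thickness))
    ht = np.zeros(len(w), complex)
    hr = np.zeros(len(w), complex)
    for i, wi in enumerate(w):
        th = wi * thickness / velocity
        z11 = zc / (1j * np.tan(th))
        z12 = zc / (1j * np.sin(th))
        ze = h_const / (1j * wi)
        zee = 1.0 / (1j * wi * c0)
        zm = np.array([[z11, z12, ze], [z12, z11, ze], [ze, ze, zee]])

        aa, bb, cc, dd = 1 + 0j, 0j, 0j, 1 + 0j
        for lv, lr, lt in front_layers:
            phi = wi * lt / lv
            z0 = lr * lv * area
            ca, sa = np.cos(phi), np.sin(phi)
            aa, bb, cc, dd = (
                aa * ca + bb * (1j * sa / z0),
                aa * (1j * z0 * sa) + bb * ca,
                cc * ca + dd * (1j * sa / z0),
                cc * (1j * z0 * sa) + dd * ca,
            )
        zf = z_front * area
        zb = z_back * area

        # unknowns: u1 (back face), u2 (front face), I, FL, uL
        m = np.zeros((5, 5), complex)
        rhs_t = np.zeros(5, complex)
        rhs_r = np.zeros(5, complex)
        m[0] = [z11 + zb, z12, ze, 0, 0]
        m[1] = [z12, z11, ze, -aa, -bb]
        m[2] = [ze, ze, zee + source_impedance, 0, 0]
        m[3] = [0, 1, 0, cc, dd]
        m_t = m.copy()
        m_t[4] = [0, 0, 0, 1, -zf]  # FL = zf * uL (radiation into the load)
        rhs_t[2] = 1.0
        sol = np.linalg.solve(m_t, rhs_t)
        ht[i] = sol[3]

        m_r = m.copy()
        m_r[4] = [0, 0, 0, 1, -zf]  # FL - zf*uL = 2*F_inc
        rhs_r[4] = 2.0
        sol = np.linalg.solve(m_r, rhs_r)
        hr[i] = -source_impedance * sol[2]
    return ht, hr


def mason_input_impedance_unloaded(freqs, thickness, velocity, density, kt, eps_r, area):
    """Closed-form electrical input impedance of an air-loaded plate."""
    w = 2.0 * np.pi * np.asarray(freqs, dtype=float)
    c0 = eps_r * EPS0 * area / thickness
    th = w * thickness / velocity
    return (1.0 / (1j * w * c0)) * (1.0 - kt**2 * np.tan(th / 2.0) / (th / 2.0))
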