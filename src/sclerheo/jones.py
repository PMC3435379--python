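"""Jones and Mueller matrix algebra for polarization-sensitive OCT.

A Jones matrix is a 2x2 complex field-transfer matrix; a Mueller matrix is
the corresponding 4x4 real operator on Stokes vectors (I, Q, U, V).  The
module provides the building blocks of depth-resolved retardance imaging:
retarder construction, the Jones->Mueller map, the Lu-Chipman polar
decomposition (retardance extraction), eigenpolarization extraction and the
mapping of eigenvectors onto the Poincare sphere.

All functions broadcast over leading axes, so a whole B-scan of matrices can
be processed in one call; scalar use works on plain (2, 2) / (4, 4) arrays.

Conventions
-----------
Stokes components of a field ``e = (e1, e2)``::

    q = |e1|^2 - |e2|^2
    u = 2 Re(e1 conj(e2))
    v = -2 Im(e1 conj(e2))

A general elliptical retarder with retardation ``delta`` about the unit
Poincare axis ``A = (q, u, v)`` is::

    J = cos(delta/2) I + i sin(delta/2) (A . Sigma)

with ``Sigma = (sigma_z, sigma_x, sigma_y)`` (Pauli matrices matched to the
q/u/v ordering above), so the eigenvector with eigenvalue ``exp(+i delta/2)``
maps exactly onto ``+A``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DegenerateEigensystemError",
    "LuChipmanError",
    "make_linear_retarder",
    "make_retarder",
    "jones_to_mueller",
    "lu_chipman_retardance",
    "lu_chipman_retardance_stack",
    "diagonalize_jones",
    "eigenvector_to_stokes",
    "fast_axis_stokes_stack",
]


class DegenerateEigensystemError(ValueError):
    """Raised when a Jones matrix has (numerically) coincident eigenvalues."""


class LuChipmanError(ValueError):
    """Raised when the Lu-Chipman decomposition degenerates
    (diattenuation magnitude >= 1 or a singular depolarizer factor)."""


# Pauli matrices ordered to match the (q, u, v) Stokes convention above.
_SIGMA_Q = np.array([[1.0, 0.0], [0.0, -1.0]], dtype=complex)
_SIGMA_U = np.array([[0.0, 1.0], [1.0, 0.0]], dtype=complex)
_SIGMA_V = np.array([[0.0, -1.0j], [1.0j, 0.0]], dtype=complex)

# Stokes-basis change matrix A in M = A (J kron conj(J)) A^-1; documented
# here explicitly: rows express (I, Q, U, V) in the coherency basis.
_A = np.array(
    [
        [1.0, 0.0, 0.0, 1.0],
        [1.0, 0.0, 0.0, -1.0],
        [0.0, 1.0, 1.0, 0.0],
        [0.0, 1.0j, -1.0j, 0.0],
    ],
    dtype=complex,
)
_A_INV = np.linalg.inv(_A)


def make_linear_retarder(retardation, orientation):
    """Jones matrix of a linear retarder.

    Parameters
    ----------
    retardation : float or array
        Phase retardation delta in radians; wrapped into [0, 2*pi).
    orientation : float or array
        Fast-axis orientation theta in radians (physical angle; the
        Poincare-sphere axis is at 2*theta on the equator).

    Returns
    -------
    ndarray, shape (..., 2, 2)
        ``R(theta) diag(exp(i delta/2), exp(-i delta/2)) R(-theta)`` —
        unitary with unit-magnitude determinant.
    """
    delta = np.mod(np.asarray(retardation, dtype=float), 2.0 * np.pi)
    theta = np.asarray(orientation, dtype=float)
    c, s = np.cos(theta), np.sin(theta)
    ep = np.exp(0.5j * delta)
    em = np.conj(ep)
    out = np.empty(np.broadcast(delta, theta).shape + (2, 2), dtype=complex)
    out[..., 0, 0] = ep * c * c + em * s * s
    out[..., 0, 1] = (ep - em) * c * s
    out[..., 1, 0] = (ep - em) * c * s
    out[..., 1, 1] = ep * s * s + em * c * c
    return out


def make_retarder(retardation, axis):
    """Jones matrix of an elliptical retarder about a Poincare-sphere axis.

    ``axis`` is a unit Stokes 3-vector (q, u, v) (shape (..., 3)); it is
    normalized internally.  The eigenvector with eigenvalue
    ``exp(+i delta/2)`` has Stokes vector ``+axis``.
    """
    delta = np.asarray(retardation, dtype=float)
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax, axis=-1, keepdims=True)
    c = np.cos(0.5 * delta)[..., None, None]
    s = np.sin(0.5 * delta)[..., None, None]
    sig = (
        ax[..., 0, None, None] * _SIGMA_Q
        + ax[..., 1, None, None] * _SIGMA_U
        + ax[..., 2, None, None] * _SIGMA_V
    )
    eye = np.eye(2, dtype=complex)
    return c * eye + 1.0j * s * sig


def jones_to_mueller(J):
    """Convert Jones matrices to Mueller matrices.

    Uses ``M = A (J kron conj(J)) A^-1`` with the Stokes basis
    (I, Q, U, V); the result of a physical (finite) Jones matrix is real —
    the imaginary residue is dropped.  Broadcasts over leading axes.
    """
    J = np.asarray(J, dtype=complex)
    # kron over the trailing (2, 2): K[2i+k, 2j+l] = J[i, j] conj(J)[k, l]
    K = np.einsum("...ij,...kl->...ikjl", J, np.conj(J))
    K = K.reshape(J.shape[:-2] + (4, 4))
    M = np.einsum("ab,...bc,cd->...ad", _A, K, _A_INV)
    return np.real(M)


def _lu_chipman_core(M):
    """Vectorized Lu-Chipman retardance.

    Returns ``(retardance, retarder_block_3x3, valid)``; invalid entries
    (diattenuation >= 1, singular factors, non-finite input) carry
    retardance 0 and ``valid=False`` instead of raising.
    """
    M = np.asarray(M, dtype=float)
    lead = M.shape[:-2]
    M = M.reshape((-1, 4, 4))
    n = M.shape[0]
    valid = np.all(np.isfinite(M), axis=(1, 2)) & (M[:, 0, 0] > 0)

    m00 = np.where(M[:, 0, 0] > 0, M[:, 0, 0], 1.0)
    Mn = M / m00[:, None, None]

    # diattenuation vector and diattenuator factor M_D
    D = Mn[:, 0, 1:4]
    d = np.linalg.norm(D, axis=1)
    valid &= d < 1.0 - 1e-12
    d_safe = np.where(d > 0, d, 1.0)
    Dhat = np.where(d[:, None] > 0, D / d_safe[:, None], 0.0)
    sq = np.sqrt(np.clip(1.0 - d**2, 0.0, None))
    mD = sq[:, None, None] * np.eye(3) + (1.0 - sq)[:, None, None] * np.einsum(
        "ni,nj->nij", Dhat, Dhat
    )
    MD = np.zeros((n, 4, 4))
    MD[:, 0, 0] = 1.0
    MD[:, 0, 1:] = D
    MD[:, 1:, 0] = D
    MD[:, 1:, 1:] = mD

    MD_use = np.where(valid[:, None, None], MD, np.eye(4))
    Mprime = Mn @ np.linalg.inv(MD_use)
    mp = Mprime[:, 1:, 1:]

    # depolarizer magnitude from the symmetric product mp mp^T
    mmT = mp @ np.transpose(mp, (0, 2, 1))
    lam = np.linalg.eigvalsh(mmT)  # ascending, >= 0
    lam = np.clip(lam, 0.0, None)
    r1, r2, r3 = np.sqrt(lam[:, 2]), np.sqrt(lam[:, 1]), np.sqrt(lam[:, 0])
    det_mp = np.linalg.det(mp)
    sign = np.where(det_mp < 0, -1.0, 1.0)
    B1 = mmT + (r1 * r2 + r2 * r3 + r3 * r1)[:, None, None] * np.eye(3)
    B2 = (r1 + r2 + r3)[:, None, None] * mmT + (r1 * r2 * r3)[:, None, None] * np.eye(3)
    detB1 = np.linalg.det(B1)
    valid &= np.abs(detB1) > 1e-300
    B1_use = np.where(valid[:, None, None], B1, np.eye(3))
    m_delta = sign[:, None, None] * (np.linalg.inv(B1_use) @ B2)
    det_mdelta = np.linalg.det(m_delta)
    valid &= np.abs(det_mdelta) > 1e-300
    m_delta_use = np.where(valid[:, None, None], m_delta, np.eye(3))
    mR = np.linalg.inv(m_delta_use) @ mp

    tr = np.trace(mR, axis1=1, axis2=2)
    ret = np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))
    ret = np.where(valid, ret, 0.0)
    return ret.reshape(lead), mR.reshape(lead + (3, 3)), valid.reshape(lead)


def lu_chipman_retardance_stack(M):
    """Retardance (radians, in [0, pi]) per matrix plus a validity mask.

    Vectorized form of :func:`lu_chipman_retardance` for pipeline use;
    degenerate pixels are flagged rather than raising.
    """
    ret, _, valid = _lu_chipman_core(M)
    return ret, valid


def lu_chipman_retardance(M):
    """Lu-Chipman polar decomposition: retardance of a single Mueller matrix.

    Decomposes ``M = M_Delta M_R M_D`` (depolarizer, retarder,
    diattenuator) and returns ``(retardance, M_R)`` where
    ``retardance = arccos(tr(M_R)/2 - 1)`` clamped to [0, pi] and ``M_R``
    is the full 4x4 retarder factor.

    Raises
    ------
    LuChipmanError
        If the diattenuation magnitude is >= 1 or a factor is singular
        (e.g. M derived from a singular Jones matrix).
    """
    ret, mR, valid = _lu_chipman_core(M)
    if ret.ndim == 0:
        if not bool(valid):
            raise LuChipmanError("degenerate Lu-Chipman decomposition")
        MR = np.eye(4)
        MR[1:, 1:] = mR
        return float(ret), MR
    if not np.all(valid):
        raise LuChipmanError("degenerate Lu-Chipman decomposition in stack")
    MR = np.zeros(ret.shape + (4, 4))
    MR[..., 0, 0] = 1.0
    MR[..., 1:, 1:] = mR
    return ret, MR


def diagonalize_jones(J, degeneracy_rtol=1e-12):
    """Eigendecomposition of a single Jones matrix with a fixed ordering.

    The eigenvector whose eigenvalue has the larger principal phase (in
    (-pi, pi]) is first; ties are broken by larger modulus.  Eigenvectors
    are unit norm.

    Raises
    ------
    DegenerateEigensystemError
        If ``|lambda1 - lambda2| < degeneracy_rtol * max|lambda|``.
    """
    J = np.asarray(J, dtype=complex)
    w, V = np.linalg.eig(J)
    scale = np.max(np.abs(w))
    if np.abs(w[0] - w[1]) < degeneracy_rtol * max(scale, 1e-300):
        raise DegenerateEigensystemError(
            f"near-degenerate eigensystem: eigenvalues {w[0]} and {w[1]}"
        )
    ph = np.angle(w)
    if (ph[1] > ph[0]) or (ph[1] == ph[0] and np.abs(w[1]) > np.abs(w[0])):
        order = [1, 0]
    else:
        order = [0, 1]
    w = w[order]
    V = V[:, order]
    V = V / np.linalg.norm(V, axis=0, keepdims=True)
    return (w[0], w[1]), (V[:, 0], V[:, 1])


def eigenvector_to_stokes(e, disambiguate=True):
    """Map a polarization eigenvector onto the Poincare sphere.

    Returns the unit Stokes 3-vector (q, u, v).  With
    ``disambiguate=True`` the vector is folded to a canonical hemisphere
    (negated if q < 0, or q == 0 and u < 0, or q == u == 0 and v < 0) so
    the two orthogonal eigenpolarizations of one retarder — Poincare
    antipodes — map to the same axis representative.
    """
    e = np.asarray(e, dtype=complex)
    nrm2 = float(np.real(np.vdot(e, e)))
    if nrm2 <= 0.0 or not np.isfinite(nrm2):
        raise ValueError("zero or non-finite eigenvector")
    q = (np.abs(e[0]) ** 2 - np.abs(e[1]) ** 2) / nrm2
    cross = e[0] * np.conj(e[1])
    u = 2.0 * np.real(cross) / nrm2
    v = -2.0 * np.imag(cross) / nrm2
    s = np.array([q, u, v])
    if disambiguate:
        if s[0] < 0 or (s[0] == 0 and s[1] < 0) or (s[0] == 0 and s[1] == 0 and s[2] < 0):
            s = -s
    return s


def fast_axis_stokes_stack(J, degeneracy_rtol=1e-9):
    """Stokes axis of the fast eigenpolarization for a stack of matrices.

    The eigenvector whose eigenvalue leads its partner in phase
    (``arg(lambda_i / lambda_j)`` in (0, pi) — the ``exp(+i delta/2)``
    branch for a retarder) is kept; the relative phase makes the choice
    independent of any global phase on the matrix.  This deterministic
    phase-ordering picks one consistent axis per retarder without folding
    antipodal axes together, which is what optic-axis-uniformity mapping
    needs.

    Returns ``(stokes, valid)`` with ``stokes`` shaped (..., 3); pixels with
    near-degenerate eigensystems or vanishing determinant are flagged.
    """
    J = np.asarray(J, dtype=complex)
    lead = J.shape[:-2]
    Jf = J.reshape((-1, 2, 2))
    det = np.linalg.det(Jf)
    valid = np.abs(det) > 1e-300
    w, V = np.linalg.eig(Jf)
    scale = np.max(np.abs(w), axis=1)
    valid &= np.abs(w[:, 0] - w[:, 1]) > degeneracy_rtol * np.maximum(scale, 1e-300)
    # relative eigenvalue phase: arg(lambda_i / lambda_other) in (0, pi)
    # marks the exp(+i delta/2) branch independently of any global phase
    ratio = np.where(
        np.abs(w[:, 1]) > 0, w[:, 0] / np.where(np.abs(w[:, 1]) > 0, w[:, 1], 1.0), 1.0
    )
    rel = np.angle(ratio)
    pick = np.where((rel > 0) & (rel < np.pi), 0, 1)
    e = V[np.arange(Jf.shape[0]), :, pick]
    nrm2 = np.real(np.einsum("ni,ni->n", np.conj(e), e))
    nrm2 = np.where(nrm2 > 0, nrm2, 1.0)
    cross = e[:, 0] * np.conj(e[:, 1])
    stokes = np.stack(
        [
            (np.abs(e[:, 0]) ** 2 - np.abs(e[:, 1]) ** 2) / nrm2,
            2.0 * np.real(cross) / nrm2,
            -2.0 * np.imag(cross) / nrm2,
        ],
        axis=-1,
    )
    return stokes.reshape(lead + (3,)), valid.reshape(lead)
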