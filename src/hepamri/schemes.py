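"""Acquisition schemes for the three functional liver MR series.

The pipeline analyses three co-registered series per animal:

* an 11-b-value diffusion-weighted series for intravoxel-incoherent-motion
  (IVIM) analysis,
* a 13-volume diffusion-tensor series (one b=0 volume plus 12 directions
  at b=500 s/mm^2),
* a 9-echo multi-echo gradient-echo series for R2* relaxometry.

Each scheme is a small validated container; the module-level defaults
reproduce the acquisition protocols the analysis was designed around.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "BValueScheme",
    "GradientScheme",
    "EchoScheme",
    "DEFAULT_IVIM_BVALUES",
    "DEFAULT_DTI_BVALUE",
    "DEFAULT_ECHO_TIMES_MS",
    "default_ivim_scheme",
    "default_dti_scheme",
    "default_echo_scheme",
    "load_default_directions",
]

#: Diffusion weightings of the IVIM protocol (s/mm^2).
DEFAULT_IVIM_BVALUES: tuple[float, ...] = (
    0.0, 20.0, 40.0, 60.0, 80.0, 100.0, 150.0, 200.0, 400.0, 600.0, 800.0,
)

#: Diffusion weighting of the tensor shell (s/mm^2).
DEFAULT_DTI_BVALUE: float = 500.0

#: Echo times of the gradient-echo series (ms), 9 evenly spaced echoes
#: spanning 2.57-24.25 ms.
DEFAULT_ECHO_TIMES_MS: tuple[float, ...] = tuple(
    np.round(np.linspace(2.57, 24.25, 9), 6)
)


def load_default_directions() -> np.ndarray:
    """Load the packaged 12-direction gradient table.

    The directions were obtained by electrostatic-repulsion optimization
    with antipodal symmetry; they are unit vectors whose second-order
    design matrix has full rank 6.
    """
    text = (
        resources.files("hepamri.data").joinpath("directions12.txt").read_text()
    )
    rows = [
        [float(x) for x in line.split()]
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
    dirs = np.asarray(rows, dtype=float)
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


@dataclass(frozen=True)
class BValueScheme:
    """Ordered diffusion weightings for an IVIM series.

    The first entry must be 0 and the list strictly increasing.
    """

    b: np.ndarray = field(
        default_factory=lambda: np.asarray(DEFAULT_IVIM_BVALUES)
    )

    def __post_init__(self) -> None:
        b = np.asarray(self.b, dtype=float)
        object.__setattr__(self, "b", b)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("b-value scheme needs at least two entries")
        if b[0] != 0.0:
            raise ValueError("first b value must be 0")
        if np.any(np.diff(b) <= 0):
            raise ValueError("b values must be strictly increasing")

    def __len__(self) -> int:
        return int(self.b.size)


@dataclass(frozen=True)
class GradientScheme:
    """b=0 plus a single diffusion-weighted shell with unit directions.

    ``directions`` is (n, 3); every row must be unit-norm to 1e-6 and the
    set must span all six independent tensor components (design matrix
    rank 6).
    """

    directions: np.ndarray = field(default_factory=load_default_directions)
    b_low: float = 0.0
    b_high: float = DEFAULT_DTI_BVALUE

    def __post_init__(self) -> None:
        d = np.asarray(self.directions, dtype=float)
        object.__setattr__(self, "directions", d)
        if d.ndim != 2 or d.shape[1] != 3:
            raise ValueError("directions must be an (n, 3) array")
        norms = np.linalg.norm(d, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("gradient directions must be unit-norm to 1e-6")
        if self.b_high <= self.b_low:
            raise ValueError("b_high must exceed b_low")
        if np.linalg.matrix_rank(self.design_matrix()) < 6:
            raise ValueError(
                "direction set is rank-deficient for tensor estimation"
            )

    def design_matrix(self) -> np.ndarray:
        """Second-order design matrix, one row per direction.

        Columns are ordered (xx, yy, zz, xy, xz, yz) with the off-diagonal
        columns doubled, so that ``row @ d6`` equals g^T D g for the tensor
        packed as ``d6 = (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)``.
        """
        g = self.directions
        return np.stack(
            [
                g[:, 0] ** 2,
                g[:, 1] ** 2,
                g[:, 2] ** 2,
                2 * g[:, 0] * g[:, 1],
                2 * g[:, 0] * g[:, 2],
                2 * g[:, 1] * g[:, 2],
            ],
            axis=1,
        )

    def __len__(self) -> int:
        # one b_low volume plus one volume per direction
        return int(self.directions.shape[0]) + 1


@dataclass(frozen=True)
class EchoScheme:
    """Ordered echo times in milliseconds for the gradient-echo series."""

    te_ms: np.ndarray = field(
        default_factory=lambda: np.asarray(DEFAULT_ECHO_TIMES_MS)
    )

    def __post_init__(self) -> None:
        te = np.asarray(self.te_ms, dtype=float)
        object.__setattr__(self, "te_ms", te)
        if te.ndim != 1 or te.size < 3:
            raise ValueError("need at least 3 echoes for a stable fit")
        if np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be positive, strictly increasing")

    def __len__(self) -> int:
        return int(self.te_ms.size)


def default_ivim_scheme() -> BValueScheme:
    return BValueScheme()


def default_dti_scheme() -> GradientScheme:
    return GradientScheme()


def default_echo_scheme() -> EchoScheme:
    return EchoScheme()
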