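"""Dirichlet mixture priors over amino-acid column compositions.

Parses the UCSC flat-file format (``Mixture=``, ``Alpha=``, ``Order =``
keyword lines, ``Background=`` optional, ``#``/``Comment`` lines ignored)
used by the published protein mixtures such as ``recode3.20comp``.

``Alpha=`` lines in the published files carry 21 numbers — the concentration
|alpha| followed by the 20 per-residue parameters; a bare 20-number form is
also accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msa_io import AMINO_ACIDS

N_AA = 20


class MixtureParseError(ValueError):
    """Raised when a Dirichlet-mixture file violates the format contract."""


@dataclass
class DirichletMixture:
    """Mixture of Dirichlet densities plus background residue frequencies.

    Attributes
    ----------
    weights:
        Mixture coefficients, shape ``(J,)``, summing to 1.
    alpha:
        Dirichlet parameters, shape ``(J, 20)``, strictly positive, columns
        ordered by :data:`leonbis.msa_io.AMINO_ACIDS` (the file's ``Order``
        line is re-mapped to this canonical order at parse time).
    background:
        Background frequencies ``p``, shape ``(20,)``, summing to 1. When the
        file has no ``Background`` line this is the mixture-implied marginal
        ``p_a = sum_j q_j * alpha_ja / |alpha_j|``, which makes the BILD score
        of any single observation exactly zero.
    """

    weights: np.ndarray
    alpha: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.alpha = np.atleast_2d(np.asarray(self.alpha, dtype=float))
        if self.weights.ndim != 1 or self.weights.size < 1:
            raise MixtureParseError("mixture needs at least one component")
        if self.alpha.shape != (self.weights.size, N_AA):
            raise MixtureParseError(
                f"alpha shape {self.alpha.shape} does not match "
                f"{self.weights.size} components x {N_AA} residues"
            )
        if not np.all(self.alpha > 0):
            raise MixtureParseError("all Dirichlet parameters must be positive")
        if abs(self.weights.sum() - 1.0) > 1e-6:
            raise MixtureParseError(
                f"mixture weights sum to {self.weights.sum():.8f}, expected 1"
            )
        if self.background is None:
            self.background = self.implied_marginal()
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (N_AA,) or abs(self.background.sum() - 1.0) > 1e-6:
            raise MixtureParseError("background must be 20 frequencies summing to 1")
        # exact-normalised copies; file truncation leaves ~1e-7 residuals
        self.weights = self.weights / self.weights.sum()
        self.background = self.background / self.background.sum()
        self.alpha_sum = self.alpha.sum(axis=1)

    @property
    def n_components(self) -> int:
        return self.weights.size

    def implied_marginal(self) -> np.ndarray:
        marg = (self.weights[:, None] * self.alpha / self.alpha.sum(axis=1)[:, None]).sum(axis=0)
        return marg / marg.sum()


def uniform_mixture(concentration: float = 1.0) -> DirichletMixture:
    """Single symmetric-Dirichlet component; handy closed-form reference."""
    return DirichletMixture(
        weights=np.ones(1),
        alpha=np.full((1, N_AA), concentration),
        background=np.full(N_AA, 1.0 / N_AA),
    )


def _parse_numbers(payload: str) -> list[float]:
    try:
        return [float(tok) for tok in payload.split()]
    except ValueError as exc:
        raise MixtureParseError(f"bad numeric field: {payload!r}") from exc


def parse_dirichlet_mixture(path) -> DirichletMixture:
    """Parse a UCSC-format Dirichlet mixture file.

    Component order follows the file; residue order is re-mapped from the
    file's ``Order`` line to the canonical alphabetical order used package
    wide. Errors out on missing ``Order``, non-positive alphas or weights not
    summing to 1 within 1e-6.
    """
    order: str | None = None
    background: np.ndarray | None = None
    weights: list[float] = []
    alphas: list[np.ndarray] = []

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith(("#", "Comment", "EndClassName")):
                continue
            if "=" not in line:
                continue
            key, _, payload = line.partition("=")
            key = key.strip().lower()
            if key == "order":
                letters = "".join(payload.split()).upper()
                if sorted(letters) != sorted(AMINO_ACIDS) or len(letters) != N_AA:
                    raise MixtureParseError(
                        f"Order line must list the 20 amino acids once each, got {letters!r}"
                    )
                order = letters
            elif key == "mixture":
                vals = _parse_numbers(payload)
                if len(vals) != 1:
                    raise MixtureParseError(f"Mixture line must hold one weight: {line!r}")
                weights.append(vals[0])
            elif key == "alpha":
                vals = _parse_numbers(payload)
                if len(vals) == N_AA + 1:
                    total, comps = vals[0], np.asarray(vals[1:])
                    if total > 0 and abs(comps.sum() - total) > 1e-3 * max(total, 1.0):
                        raise MixtureParseError(
                            f"Alpha line: leading |alpha|={total} does not match "
                            f"component sum {comps.sum():.6f}"
                        )
                elif len(vals) == N_AA:
                    comps = np.asarray(vals)
                else:
                    raise MixtureParseError(
                        f"Alpha line must hold 20 or 21 numbers, got {len(vals)}"
                    )
                alphas.append(comps)
            elif key == "background":
                vals = _parse_numbers(payload)
                if len(vals) != N_AA:
                    raise MixtureParseError("Background line must hold 20 frequencies")
                background = np.asarray(vals)

    if order is None:
        raise MixtureParseError(f"{path}: missing Order line")
    if not alphas:
        raise MixtureParseError(f"{path}: no Alpha lines found")
    if len(weights) != len(alphas):
        raise MixtureParseError(
            f"{path}: {len(weights)} Mixture lines but {len(alphas)} Alpha lines"
        )

    # re-map file residue order -> canonical AMINO_ACIDS order
    perm = np.asarray([order.index(a) for a in AMINO_ACIDS])
    alpha = np.vstack(alphas)[:, perm]
    if background is not None:
        background = background[perm]
    return DirichletMixture(np.asarray(weights), alpha, background)
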