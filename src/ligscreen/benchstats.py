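"""Enrichment-curve benchmarking of ranked active/decoy lists.

An enrichment curve plots, against the fraction x of a ranked database
examined, the fraction y(x) of all known actives found so far.  Screening
quality is summarised by the trapezoidal integral of the difference between
a method's curve and a baseline (the diagonal y = x for expected random
selection); positive values mean the method beats random picking.  Axes are
fractions in [0, 1].  A Tanimoto bitset similarity rounds out the toolbox
for fingerprint-based ligand comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import LigscreenError


@dataclass
class EnrichmentCurve:
    """x: fraction of list examined (step 1/n); y: fraction of actives found."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")

    @property
    def n(self) -> int:
        return self.x.size


def _as_active_flags(ranked_labels) -> np.ndarray:
    flags = []
    for lab in ranked_labels:
        if isinstance(lab, str):
            flags.append(lab.strip().lower() in ("active", "a", "1", "true"))
        else:
            flags.append(bool(lab))
    return np.asarray(flags, dtype=bool)


def enrichment_curve(ranked_labels) -> EnrichmentCurve:
    """Cumulative active fraction along a ranked label list (best first)."""
    flags = _as_active_flags(ranked_labels)
    if flags.size == 0:
        raise LigscreenError("ranked list is empty")
    n_active = int(flags.sum())
    if n_active == 0:
        raise LigscreenError("enrichment curve undefined without actives")
    n = flags.size
    x = np.arange(1, n + 1) / n
    y = np.cumsum(flags) / n_active
    return EnrichmentCurve(x=x, y=y)


def random_baseline(n_active: int, n_total: int, mode: str = "expected",
                    seed: int = 0) -> EnrichmentCurve:
    """Random-selection baseline: the diagonal (expected) or one seeded
    uniform shuffle (sampled)."""
    if not 0 < n_active <= n_total:
        raise LigscreenError("need 0 < n_active <= n_total")
    if mode == "expected":
        x = np.arange(1, n_total + 1) / n_total
        return EnrichmentCurve(x=x, y=x.copy())
    if mode == "sampled":
        rng = np.random.default_rng(seed)
        labels = np.zeros(n_total, dtype=bool)
        labels[:n_active] = True
        rng.shuffle(labels)
        return enrichment_curve(labels)
    raise LigscreenError(f"unknown mode '{mode}'")


def difference_integral(curve_a: EnrichmentCurve,
                        curve_b: EnrichmentCurve) -> float:
    """Trapezoidal ∫₀¹ (y_a − y_b) dx on the shared fractional axis.

    Both curves implicitly start at (0, 0).
    """
    if curve_a.n != curve_b.n:
        raise LigscreenError("curves must come from equal-length lists")
    x = np.concatenate([[0.0], curve_a.x])
    diff = np.concatenate([[0.0], curve_a.y - curve_b.y])
    return float(np.trapezoid(diff, x))


def active_to_decoy_percent(n_active: int, n_decoy: int) -> float:
    """Actives-to-decoys ratio in percent (the odds of a random pick
    landing on an active, quoted against the decoy pool)."""
    if n_decoy <= 0:
        raise LigscreenError("n_decoy must be positive")
    return 100.0 * n_active / n_decoy


def promotion_percent(n_promoted: int, n_total: int) -> float:
    """Share of the full set promoted to the next stage, in percent."""
    if n_total <= 0:
        raise LigscreenError("n_total must be positive")
    return 100.0 * n_promoted / n_total


def tanimoto(fp_a, fp_b) -> float:
    """Tanimoto similarity |a∧b| / |a∨b| of two equal-length bitsets."""
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise LigscreenError("fingerprints must have equal length")
    union = np.count_nonzero(a | b)
    if union == 0:
        raise LigscreenError("Tanimoto undefined for two empty fingerprints")
    return float(np.count_nonzero(a & b) / union)
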