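"""Sliding heptad-window coiled-coil prediction.

The classical procedure: slide a window of 14/21/28 residues along the
sequence; for each placement try all 7 heptad frames; the window score is the
geometric mean of per-residue propensities for their frame-assigned heptad
positions (optionally up-weighting the core a/d positions). Each residue's
raw score is the maximum over every window placement covering it and every
frame. The raw score is converted to a CC-formation probability via the ratio
of two Gaussian densities (coiled-coil vs globular score distributions) with
a 30:1 globular prior:

    p(s) = g_cc(s) / (g_cc(s) + 30 · g_glob(s))

Residues near the ends are covered by fewer placements and simply take the
max over those available — the natural behaviour on C-terminal fragments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._coils_data import (
    AD_WEIGHT,
    GAUSSIAN_CALIBRATION,
    HEPTAD,
    MTIDK,
    PRIOR_RATIO,
    SUPPORTED_WINDOWS,
)
from .sequences import ProteinSequence

_MATRICES = {"mtidk": MTIDK}


class CoilsError(ValueError):
    """Raised for unsupported parameters or unscorable sequences."""


@dataclass(frozen=True)
class CoilsParams:
    """Scoring parameters: window length, propensity table, a/d weighting."""

    window: int = 14
    matrix: str = "mtidk"
    ad_weighting: bool = True

    def __post_init__(self) -> None:
        if self.window not in SUPPORTED_WINDOWS:
            raise CoilsError(
                f"unsupported window {self.window}; supported: {SUPPORTED_WINDOWS}"
            )
        if self.matrix not in _MATRICES:
            raise CoilsError(f"unknown propensity matrix {self.matrix!r}")
        if self.calibration_key not in GAUSSIAN_CALIBRATION:
            raise CoilsError(
                f"no Gaussian calibration for {self.calibration_key}"
            )

    @property
    def calibration_key(self) -> tuple[str, int, bool]:
        return (self.matrix, self.window, self.ad_weighting)

    @property
    def calibration(self) -> tuple[float, float, float, float]:
        """(m_cc, sd_cc, m_glob, sd_glob) for this parameter triple."""
        cal = GAUSSIAN_CALIBRATION[self.calibration_key]
        m_cc, sd_cc, m_g, sd_g = cal
        if sd_cc <= 0 or sd_g <= 0:
            raise CoilsError(f"degenerate calibration for {self.calibration_key}")
        return cal


@dataclass(frozen=True)
class Segment:
    """A contiguous run of residues above the probability threshold."""

    start: int  # full-length numbering, inclusive
    end: int    # inclusive
    peak_probability: float


@dataclass(frozen=True)
class CoilsProfile:
    """Per-residue CC scores/probabilities for one sequence at one window."""

    sequence_id: str
    params: CoilsParams
    offsets: np.ndarray          # full-length residue numbers
    residues: str
    raw_scores: np.ndarray       # >= 0, one per residue
    probabilities: np.ndarray    # in [0, 1]
    registers: str               # heptad letter a-g of the best-scoring frame
    segment_threshold: float = 0.5
    segments: tuple[Segment, ...] = ()

    @property
    def max_probability(self) -> float:
        return float(self.probabilities.max())

    @property
    def max_score(self) -> float:
        return float(self.raw_scores.max())

    def to_records(self) -> list[dict]:
        return [
            {
                "position": int(self.offsets[i]),
                "aa": self.residues[i],
                "register": self.registers[i],
                "score": float(self.raw_scores[i]),
                "probability": float(self.probabilities[i]),
            }
            for i in range(len(self.residues))
        ]

    def summary(self) -> dict:
        return {
            "sequence_id": self.sequence_id,
            "window": self.params.window,
            "matrix": self.params.matrix,
            "ad_weighting": self.params.ad_weighting,
            "max_probability": self.max_probability,
            "max_score": self.max_score,
            "segment_threshold": self.segment_threshold,
            "segments": [
                {"start": s.start, "end": s.end, "peak_probability": s.peak_probability}
                for s in self.segments
            ],
        }


# Probability above which a run of residues is reported as a predicted CC
# segment. On the frozen calibration the native Orai1 C-terminal coil sits
# clearly above and the 1-266/1-275 truncations clearly below this line; see
# docs/methods.md.
DEFAULT_SEGMENT_THRESHOLD = 0.5


def _log_propensities(residues: str, matrix: str) -> np.ndarray:
    """(L, 7) natural-log propensities, floored to keep zeros finite."""
    table = _MATRICES[matrix]
    out = np.empty((len(residues), 7))
    for i, aa in enumerate(residues):
        try:
            out[i] = table[aa]
        except KeyError:
            raise CoilsError(f"residue {aa!r} not in matrix {matrix!r}") from None
    return np.log(np.maximum(out, 1e-4))


def window_scores(seq: ProteinSequence, params: CoilsParams
                  ) -> tuple[np.ndarray, str]:
    """Per-residue raw scores and best-frame heptad registers.

    score(window, frame) = weighted geometric mean of propensities; each
    residue takes the max over all covering placements × frames. Ties prefer
    the earlier placement, then the lower frame index.
    """
    w = params.window
    L = len(seq.residues)
    if L < w:
        raise CoilsError(
            f"{seq.id}: sequence length {L} shorter than window {w}"
        )
    logp = _log_propensities(seq.residues, params.matrix)
    weights = np.ones(7)
    if params.ad_weighting:
        weights[HEPTAD.index("a")] = AD_WEIGHT
        weights[HEPTAD.index("d")] = AD_WEIGHT

    best = np.full(L, -np.inf)
    best_reg = [0] * L
    n_starts = L - w + 1
    # positions j within window, heptad index (frame + j) % 7
    j = np.arange(w)
    for frame in range(7):
        hept = (frame + j) % 7
        wts = weights[hept]
        denom = wts.sum()
        # per-start weighted log-propensity sums for this frame
        mat = np.empty((n_starts, w))
        for jj in range(w):
            mat[:, jj] = logp[jj: jj + n_starts, hept[jj]] * wts[jj]
        scores = np.exp(mat.sum(axis=1) / denom)
        for i0 in range(n_starts):
            s = scores[i0]
            span = slice(i0, i0 + w)
            improved = s > best[span]
            if improved.any():
                idx = np.nonzero(improved)[0] + i0
                best[idx] = s
                for k, ii in enumerate(idx):
                    best_reg[ii] = hept[ii - i0]
    registers = "".join(HEPTAD[r] for r in best_reg)
    return best, registers


def score_to_probability(raw_score, params: CoilsParams):
    """CC-formation probability from the two-Gaussian density ratio.

    Strictly increasing on raw_score >= 0 for the frozen calibration; equals
    0.5 where the prior-weighted densities are equal. Accepts scalars or
    arrays.
    """
    m_cc, sd_cc, m_g, sd_g = params.calibration
    x = np.asarray(raw_score, dtype=float)
    log_gcc = -0.5 * ((x - m_cc) / sd_cc) ** 2 - np.log(sd_cc)
    log_gg = -0.5 * ((x - m_g) / sd_g) ** 2 - np.log(sd_g)
    # p = gcc / (gcc + R*gg) = 1 / (1 + exp(log R + log gg - log gcc))
    z = np.log(PRIOR_RATIO) + log_gg - log_gcc
    p = 1.0 / (1.0 + np.exp(np.clip(z, -700, 700)))
    if np.isscalar(raw_score) or np.ndim(raw_score) == 0:
        return float(p)
    return p


def _find_segments(offsets: np.ndarray, probs: np.ndarray, threshold: float
                   ) -> tuple[Segment, ...]:
    segments = []
    above = probs >= threshold
    i = 0
    n = len(probs)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            segments.append(
                Segment(
                    start=int(offsets[i]),
                    end=int(offsets[j]),
                    peak_probability=float(probs[i: j + 1].max()),
                )
            )
            i = j + 1
        else:
            i += 1
    return tuple(segments)


def predict(seq: ProteinSequence, params: CoilsParams | None = None,
            segment_threshold: float = DEFAULT_SEGMENT_THRESHOLD) -> CoilsProfile:
    """Full profile: raw scores, probabilities, registers and CC segments."""
    params = params or CoilsParams()
    raw, registers = window_scores(seq, params)
    probs = score_to_probability(raw, params)
    offsets = np.arange(seq.numbering_offset, seq.end + 1)
    return CoilsProfile(
        sequence_id=seq.id,
        params=params,
        offsets=offsets,
        residues=seq.residues,
        raw_scores=raw,
        probabilities=probs,
        registers=registers,
        segment_threshold=segment_threshold,
        segments=_find_segments(offsets, probs, segment_threshold),
    )


def scan_windows(seq: ProteinSequence, params_base: CoilsParams | None = None,
                 windows: tuple[int, ...] = SUPPORTED_WINDOWS,
                 segment_threshold: float = DEFAULT_SEGMENT_THRESHOLD,
                 ) -> tuple[int, CoilsProfile]:
    """Profile at the window whose max probability is largest.

    Ties break toward the smallest window. The sequence must be at least as
    long as the largest requested window.
    """
    base = params_base or CoilsParams()
    for w in windows:
        if w not in SUPPORTED_WINDOWS:
            raise CoilsError(f"unsupported window {w}")
    if len(seq.residues) < max(windows):
        raise CoilsError(
            f"{seq.id}: length {len(seq.residues)} shorter than the largest "
            f"window {max(windows)}"
        )
    best_profile = None
    for w in sorted(windows):
        profile = predict(
            seq,
            CoilsParams(window=w, matrix=base.matrix, ad_weighting=base.ad_weighting),
            segment_threshold,
        )
        if best_profile is None or profile.max_probability > best_profile.max_probability:
            best_profile = profile
    return best_profile.params.window, best_profile


def mutant_delta(profile_wt: CoilsProfile, profile_mut: CoilsProfile,
                 tolerance: float = 0.01) -> tuple[float, str]:
    """Signed change in max CC probability (mutant − WT) and a verdict.

    Verdict is "stabilized" / "destabilized" / "unchanged" by a symmetric
    tolerance on the probability scale. Both profiles must share params.
    """
    if profile_wt.params != profile_mut.params:
        raise CoilsError(
            f"params mismatch: {profile_wt.params} vs {profile_mut.params}"
        )
    delta = profile_mut.max_probability - profile_wt.max_probability
    if delta > tolerance:
        verdict = "stabilized"
    elif delta < -tolerance:
        verdict = "destabilized"
    else:
        verdict = "unchanged"
    return delta, verdict


def profile_to_csv(profile: CoilsProfile, path: str | Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["position", "aa", "register", "score", "probability"]
        )
        writer.writeheader()
        writer.writerows(profile.to_records())


def summary_to_json(profile: CoilsProfile, path: str | Path,
                    best_window: int | None = None) -> None:
    summary = profile.summary()
    if best_window is not None:
        summary["best_window"] = best_window
    Path(path).write_text(json.dumps(summary, indent=2) + "\n")
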