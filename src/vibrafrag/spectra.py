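"""Broadened IR spectra, peak assignment matching, and MAE/RMSE scoring.

The comparison statistics are the mean absolute error and root-mean-square
error over matched experimental/calculated wavenumber pairs, optionally
decomposed into functional-group (FG) and non-functional-group (NFG)
vibrations — FG meaning the mode label involves an X–H (X ∈ N, O, S) or
carbonyl-type motion, the moieties that participate in hydrogen bonding.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import InvalidArgumentError
from .normal_modes import round_half_up

DEFAULT_GRID = np.arange(400.0, 4001.0, 1.0)


@dataclass
class Spectrum:
    grid: np.ndarray          # cm⁻¹, strictly increasing
    absorbance: np.ndarray    # arbitrary units, >= 0

    def __post_init__(self):
        self.grid = np.asarray(self.grid, float)
        self.absorbance = np.asarray(self.absorbance, float)
        if np.any(np.diff(self.grid) <= 0):
            raise InvalidArgumentError("spectrum grid must be strictly increasing")
        if len(self.grid) != len(self.absorbance):
            raise InvalidArgumentError("grid and absorbance lengths differ")


def synthesize_spectrum(freqs, intensities=None, shape: str = "lorentzian",
                        fwhm: float = 20.0, grid: np.ndarray | None = None) -> Spectrum:
    """Sum of area-normalized line shapes; peak area ∝ intensity."""
    if fwhm <= 0:
        raise InvalidArgumentError("fwhm must be positive")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, float)
    freqs = np.asarray(list(freqs), float)
    if intensities is None:
        intensities = np.ones_like(freqs)
    intensities = np.asarray(list(intensities), float)
    if len(freqs) != len(intensities):
        raise InvalidArgumentError("frequency and intensity lists differ in length")
    if np.any(intensities < 0):
        raise InvalidArgumentError("intensities must be non-negative")
    y = np.zeros_like(grid)
    for nu0, inten in zip(freqs, intensities):
        if shape == "lorentzian":
            gamma = fwhm / 2.0
            y += inten * (gamma / np.pi) / ((grid - nu0) ** 2 + gamma**2)
        elif shape == "gaussian":
            sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            y += inten * np.exp(-((grid - nu0) ** 2) / (2 * sigma**2)) / (
                sigma * np.sqrt(2 * np.pi))
        else:
            raise InvalidArgumentError(f"unknown line shape {shape!r}")
    return Spectrum(grid, y)


# ---------------------------------------------------------------------------
# Assignment tables
# ---------------------------------------------------------------------------

@dataclass
class AssignmentTable:
    """Matched experimental/calculated wavenumber pairs with mode labels."""

    labels: list[str]
    exp: np.ndarray        # cm⁻¹
    calc: np.ndarray       # cm⁻¹
    group: list[str] | None = None      # 'FG' / 'NFG'
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.exp = np.asarray(self.exp, float)
        self.calc = np.asarray(self.calc, float)
        if not (len(self.labels) == len(self.exp) == len(self.calc)):
            raise InvalidArgumentError("labels, exp and calc must have equal length")
        if np.any(self.exp <= 0) or np.any(self.calc <= 0):
            raise InvalidArgumentError("wavenumbers must be positive")
        if any(not lb for lb in self.labels):
            raise InvalidArgumentError("labels must be nonempty")
        if self.group is not None and len(self.group) != len(self.labels):
            raise InvalidArgumentError("one group tag per row required")

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        data = {"label": self.labels, "exp_cm1": self.exp, "calc_cm1": self.calc}
        if self.group is not None:
            data["group"] = self.group
        for k, v in self.extra.items():
            data[k] = v
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AssignmentTable":
        group = list(df["group"]) if "group" in df.columns else None
        extra = {c: df[c].to_numpy() for c in df.columns
                 if c not in ("label", "exp_cm1", "calc_cm1", "group")}
        return cls(list(df["label"]), df["exp_cm1"].to_numpy(),
                   df["calc_cm1"].to_numpy(), group, extra)


_FG_PATTERNS = (
    re.compile(r"[NOS]\d*[-–]?H", re.IGNORECASE),   # N–H / O–H / S–H motions
    re.compile(r"C\d*[=]?O", re.IGNORECASE),        # carbonyl / C–O stretches
)


def assign_groups(labels: list[str]) -> list[str]:
    """Rule-based FG/NFG tagging from mode-label text (user-overridable)."""
    out = []
    for lb in labels:
        out.append("FG" if any(p.search(lb) for p in _FG_PATTERNS) else "NFG")
    return out


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    table: AssignmentTable
    unmatched_exp: list[float]
    unmatched_calc: list[float]


def match_assignments(calc, exp, window: float = 100.0,
                      strategy: str = "optimal") -> MatchResult:
    """One-to-one exp↔calc peak pairing within a wavenumber window.

    ``nearest_greedy``: visit experimental peaks from high to low wavenumber,
    each taking the nearest unused calculated peak within the window.
    ``optimal``: rectangular assignment minimizing total |exp − calc| over
    admissible pairs.
    """
    if window <= 0:
        raise InvalidArgumentError("matching window must be positive")
    calc = np.asarray(list(calc), float)
    exp = np.asarray(list(exp), float)
    pairs: list[tuple[int, int]] = []     # (exp index, calc index)
    if strategy == "nearest_greedy":
        used = np.zeros(len(calc), bool)
        for ei in np.argsort(-exp):
            diffs = np.abs(calc - exp[ei])
            diffs[used] = np.inf
            if len(diffs) and np.min(diffs) <= window:
                ci = int(np.argmin(diffs))
                used[ci] = True
                pairs.append((int(ei), ci))
    elif strategy == "optimal":
        if len(calc) and len(exp):
            cost = np.abs(exp[:, None] - calc[None, :])
            big = window * max(len(exp), len(calc)) * 10 + 1e6
            # tiny rank-crossing penalty: among total-deviation ties, prefer the
            # order-preserving (non-crossing) assignment
            rank_e = np.argsort(np.argsort(exp))
            rank_c = np.argsort(np.argsort(calc))
            tie = 1e-6 * np.abs(rank_e[:, None] - rank_c[None, :])
            masked = np.where(cost <= window, cost + tie, big)
            rows, cols = linear_sum_assignment(masked)
            pairs = [(int(r), int(c)) for r, c in zip(rows, cols)
                     if cost[r, c] <= window]
    else:
        raise InvalidArgumentError(f"unknown matching strategy {strategy!r}")

    pairs.sort(key=lambda rc: -exp[rc[0]])
    labels = [f"exp {exp[r]:.0f}" for r, _ in pairs]
    table = AssignmentTable(labels, exp[[r for r, _ in pairs]],
                            calc[[c for _, c in pairs]]) if pairs else \
        AssignmentTable([], np.empty(0).reshape(0), np.empty(0))
    matched_e = {r for r, _ in pairs}
    matched_c = {c for _, c in pairs}
    return MatchResult(table,
                       [float(v) for i, v in enumerate(exp) if i not in matched_e],
                       [float(v) for i, v in enumerate(calc) if i not in matched_c])


# ---------------------------------------------------------------------------
# Error statistics
# ---------------------------------------------------------------------------

@dataclass
class ErrorSummary:
    mae: float
    rmse: float
    n: int
    per_group: dict = field(default_factory=dict)

    def to_dict(self, ndigits: int = 2) -> dict:
        out = {"mae": round_half_up(self.mae, ndigits),
               "rmse": round_half_up(self.rmse, ndigits), "n": self.n}
        for grp, (mae, rmse, n) in self.per_group.items():
            out[grp] = {"mae": round_half_up(mae, ndigits),
                        "rmse": round_half_up(rmse, ndigits), "n": n}
        return out


def _mae_rmse(dev: np.ndarray) -> tuple[float, float]:
    return float(np.mean(np.abs(dev))), float(np.sqrt(np.mean(dev**2)))


def error_summary(t: AssignmentTable) -> ErrorSummary:
    """MAE = mean |exp − calc|; RMSE = √mean (exp − calc)²; per-group when tagged."""
    if len(t) == 0:
        raise InvalidArgumentError("cannot summarize an empty assignment table")
    dev = t.exp - t.calc
    mae, rmse = _mae_rmse(dev)
    per_group = {}
    if t.group is not None:
        for grp in ("FG", "NFG"):
            mask = np.array([g == grp for g in t.group])
            if mask.any():
                gmae, grmse = _mae_rmse(dev[mask])
                per_group[grp] = (gmae, grmse, int(mask.sum()))
    return ErrorSummary(mae, rmse, len(t), per_group)


def read_assignment_csv(path) -> AssignmentTable:
    """CSV dialect with header: label, exp_cm1, calc_cm1[, group]."""
    return AssignmentTable.from_frame(pd.read_csv(path))


def write_assignment_csv(t: AssignmentTable, path) -> None:
    t.to_frame().to_csv(path, index=False)
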