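"""50% mechanical withdrawal thresholds from von Frey up-down sessions.

The up-down (Dixon staircase) procedure presents calibrated filaments in
sequence: a withdrawal response steps the next filament down, no response
steps it up.  Testing continues until four trials after the first response
reversal (or a trial cap), and the 50% withdrawal threshold is estimated as

    threshold = 10 ** (X_f + k * delta)        [grams]

where ``X_f`` is the log10 force of the final filament, ``delta`` the mean
log10 spacing of the filament series, and ``k`` a pattern-dependent offset.
The offsets are the maximum-likelihood estimates under Dixon's model of a
normal (probit) psychometric function with spread equal to the filament
spacing; a pattern-keyed table of these offsets ships with the package
(``data/k_table.json``) and can be overridden per session.  Sessions that
never reverse (all responses positive or all negative) are censored at the
boundary filament so that group means remain computable, and are flagged.

Group summaries (mean +/- SEM per treatment group and week) and pairwise
Tukey-Kramer comparisons (studentized-range test with the unequal-n
standard error) reproduce the study-style behavioral statistics.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from pipn.errors import ValidationError

logger = logging.getLogger(__name__)

#: Standard rat von Frey filament series in grams (a convention, configurable).
DEFAULT_FILAMENTS_G: tuple[float, ...] = (0.41, 0.70, 1.20, 2.00, 3.63, 5.50, 8.50, 15.10)

_POSITIVE, _NEGATIVE = "X", "O"


def _load_default_k_table() -> dict[str, float]:
    with resources.files("pipn.data").joinpath("k_table.json").open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class ThresholdEstimate:
    """A 50% withdrawal threshold in grams, with censoring status."""

    threshold_g: float
    censored: str  # one of {"none", "floor", "ceiling"}
    n_trials: int


@dataclass
class UpDownSession:
    """One paw's ordered staircase: (log10 force, response) trials plus the
    filament series they were drawn from.

    ``delta`` defaults to the mean log10 spacing of the series; ``k_table``
    defaults to the shipped pattern-offset table.
    """

    session_id: str
    trials: list[tuple[float, bool]]
    filament_log_forces: Sequence[float]
    delta: float | None = None
    k_table: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        lf = np.asarray(self.filament_log_forces, dtype=float)
        if lf.ndim != 1 or len(lf) < 2 or not np.all(np.diff(lf) > 0):
            raise ValidationError("filament_log_forces must be ascending with >=2 entries")
        if not self.trials:
            raise ValidationError("session has no trials")
        for x, _ in self.trials:
            if not np.any(np.isclose(lf, x, atol=1e-9)):
                raise ValidationError(
                    f"trial log-force {x} is not a member of the filament series"
                )
        if self.delta is None:
            self.delta = float(np.mean(np.diff(lf)))

    @property
    def pattern(self) -> str:
        return "".join(_POSITIVE if r else _NEGATIVE for _, r in self.trials)


def session_from_forces(
    session_id: str,
    forces_g: Sequence[float],
    responses: Sequence[bool],
    filament_forces_g: Sequence[float] = DEFAULT_FILAMENTS_G,
) -> UpDownSession:
    """Build a session from forces in grams (converted to log10 internally)."""
    series = np.log10(np.asarray(filament_forces_g, dtype=float))
    trials = [(float(np.log10(f)), bool(r)) for f, r in zip(forces_g, responses, strict=True)]
    return UpDownSession(session_id, trials, series.tolist())


def _truncate(
    trials: list[tuple[float, bool]], n_after_reversal: int, max_trials: int
) -> tuple[list[tuple[float, bool]], bool]:
    """Apply the stopping rule; returns (used trials, whether extras were cut)."""
    responses = [r for _, r in trials]
    stop = min(len(trials), max_trials)
    for i in range(1, len(responses)):
        if responses[i] != responses[i - 1]:
            stop = min(stop, i + 1 + n_after_reversal)
            break
    return trials[:stop], stop < len(trials)


def dixon_k(log_forces: Sequence[float], responses: Sequence[bool], delta: float) -> float:
    """Dixon pattern offset k for an observed staircase.

    Maximum-likelihood estimate of the 50% point under a normal (probit)
    psychometric function with spread sigma = ``delta``, expressed as an
    offset from the final trial's log force in units of ``delta``.
    """
    x = np.asarray(log_forces, dtype=float)
    y = np.asarray(responses, dtype=bool)

    def nll(mu: float) -> float:
        p = stats.norm.cdf((x - mu) / delta)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -float(np.sum(np.where(y, np.log(p), np.log1p(-p))))

    span = x.max() - x.min() + 6 * delta
    res = optimize.minimize_scalar(
        nll, bounds=(x.min() - 3 * delta, x.min() - 3 * delta + span + 1e-9),
        method="bounded", options={"xatol": 1e-10},
    )
    return float((res.x - x[-1]) / delta)


def _pattern_relative_path(pattern: str) -> list[int]:
    """Filament index offsets (in steps) implied by a response pattern on an
    unbounded series: start at 0, step down after X, up after O."""
    pos = 0
    path = [0]
    for ch in pattern[:-1]:
        pos += -1 if ch == _POSITIVE else 1
        path.append(pos)
    return path


def build_k_table(max_trials: int = 9, n_after_reversal: int = 4) -> dict[str, float]:
    """Enumerate every terminal response pattern the stopping rule can
    produce (on an unbounded series) and tabulate its Dixon offset k."""
    table: dict[str, float] = {}
    for length in range(2, max_trials + 1):
        for bits in itertools.product("OX", repeat=length):
            pattern = "".join(bits)
            # terminal iff the stopping rule fires exactly at the last trial
            responses = [c == _POSITIVE for c in pattern]
            first_rev = next(
                (i for i in range(1, length) if responses[i] != responses[i - 1]), None
            )
            if first_rev is None:
                continue  # censored, no k
            stop = min(max_trials, first_rev + 1 + n_after_reversal)
            if stop != length:
                continue
            rel = _pattern_relative_path(pattern)
            table[pattern] = round(dixon_k(rel, responses, 1.0), 4)
    return table


def estimate_threshold(
    s: UpDownSession,
    n_after_reversal: int = 4,
    max_trials: int = 9,
) -> ThresholdEstimate:
    """Estimate the 50% withdrawal threshold of a session.

    Trials beyond the stopping rule are ignored with a warning.  Sessions
    with no response reversal are censored at the boundary filament force.
    The offset k comes from the session's pattern table when the pattern is
    present and the staircase never clipped at a series boundary; otherwise
    it is computed directly by :func:`dixon_k` on the observed trials.
    """
    used, cut = _truncate(s.trials, n_after_reversal, max_trials)
    if cut:
        warnings.warn(
            f"session {s.session_id}: trials beyond the stopping rule ignored",
            stacklevel=2,
        )
    responses = [r for _, r in used]
    lf = np.asarray(s.filament_log_forces, dtype=float)
    if all(responses):
        return ThresholdEstimate(float(10 ** lf[0]), "floor", len(used))
    if not any(responses):
        return ThresholdEstimate(float(10 ** lf[-1]), "ceiling", len(used))

    x_f = used[-1][0]
    delta = float(s.delta)
    pattern = "".join(_POSITIVE if r else _NEGATIVE for r in responses)
    k_table = s.k_table if s.k_table is not None else _load_default_k_table()

    k = None
    if pattern in k_table:
        # table assumes an unclipped staircase; verify the observed forces
        rel = _pattern_relative_path(pattern)
        implied = used[0][0] + np.asarray(rel) * delta
        if np.allclose(implied, [x for x, _ in used], atol=0.25 * delta):
            k = float(k_table[pattern])
    if k is None:
        k = dixon_k([x for x, _ in used], responses, delta)
    return ThresholdEstimate(float(10 ** (x_f + k * delta)), "none", len(used))


def threshold_from_final(x_f: float, k: float, delta: float) -> float:
    """The closed-form estimator 10**(X_f + k*delta) in grams."""
    return float(10 ** (x_f + k * delta))


def summarize_groups(thresholds: pd.DataFrame) -> pd.DataFrame:
    """Mean, SEM and n per (group, week) from a long-format table.

    ``thresholds`` needs columns ``group``, ``threshold_g`` and optionally
    ``week`` (a single implicit week otherwise).  SEM = sd/sqrt(n) is
    reported as NaN with a warning for single-animal cells.
    """
    df = thresholds.copy()
    if "week" not in df.columns:
        df["week"] = 0
    if df.empty:
        raise ValidationError("no threshold rows to summarize")
    rows = []
    for (group, week), sub in df.groupby(["group", "week"], sort=True):
        vals = sub["threshold_g"].to_numpy(dtype=float)
        n = len(vals)
        sem = float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else math.nan
        if n == 1:
            warnings.warn(f"group {group!r} week {week!r}: single animal, SEM undefined", stacklevel=2)
        rows.append(
            {"group": group, "week": week, "mean_g": float(np.mean(vals)), "sem_g": sem, "n": n}
        )
    return pd.DataFrame(rows)


@dataclass
class TukeyKramerResult:
    """Pairwise studentized-range comparisons plus the one-way ANOVA F."""

    comparisons: pd.DataFrame
    anova_f: float
    anova_p: float
    df_within: int


def tukey_kramer(groups: Mapping[str, Sequence[float]], alpha_levels=(0.05, 0.01)) -> TukeyKramerResult:
    """All pairwise Tukey-Kramer comparisons between treatment groups.

    For groups i, j with means m, sizes n and pooled within-group mean
    square MSW on N-k degrees of freedom:

        q_ij = |m_i - m_j| / sqrt( MSW/2 * (1/n_i + 1/n_j) )

    with p-values from the studentized range distribution q(k, N-k).  The
    one-way ANOVA F-test is computed alongside but does not gate the
    pairwise tests.
    """
    names = sorted(groups)
    if len(names) < 2:
        raise ValidationError("need >=2 groups")
    data = {g: np.asarray(groups[g], dtype=float) for g in names}
    for g, v in data.items():
        if len(v) < 2:
            raise ValidationError(f"group {g!r} needs >=2 observations")
    k = len(names)
    n_tot = sum(len(v) for v in data.values())
    df_w = n_tot - k
    grand = np.concatenate(list(data.values())).mean()
    ssw = sum(float(((v - v.mean()) ** 2).sum()) for v in data.values())
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in data.values())
    msw = ssw / df_w
    msb = ssb / (k - 1)
    if msw > 0:
        f = msb / msw
        f_p = float(stats.f.sf(f, k - 1, df_w))
    else:
        f = math.inf if msb > 0 else 0.0
        f_p = 0.0 if msb > 0 else 1.0

    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        v1, v2 = data[g1], data[g2]
        diff = float(v1.mean() - v2.mean())
        se = math.sqrt(msw / 2 * (1 / len(v1) + 1 / len(v2)))
        if se > 0:
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_w))
        else:
            q = 0.0 if diff == 0 else math.inf
            p = 1.0 if diff == 0 else 0.0
        row = {"group1": g1, "group2": g2, "diff": diff, "se": se, "q": q, "p_value": p}
        for a in alpha_levels:
            row[f"significant_{a}"] = p < a
        rows.append(row)
    return TukeyKramerResult(pd.DataFrame(rows), f, f_p, df_w)
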