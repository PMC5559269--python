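"""Canned parameter-recovery experiments.

Each experiment simulates a cohort of single-cell movies under one of the
imaging conditions the generator emulates, runs the blind analysis chain and
returns the recovered statistic next to its ground truth. Published
per-strain values (lifetime means/SDs, the static-patch percentage, the
actin-onset delay of the Myo5-end3C fusion) parameterize the generators; the
pipeline never sees them.

All randomness derives from a single integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .pipeline import analyze_cohort, analyze_movie
from .synth_movie import (STATIC, SimParams, simulate_comet_condition,
                          simulate_movie)

#: published patch lifetime distributions (mean_s, sd_s) per strain
LIFETIME_SLA1_WT = (24.1, 4.9)
LIFETIME_SLA1_W41A_W108A = (78.8, 31.2)
LIFETIME_PAN1_DPRD = (23.6, 4.2)
#: actin onset delay of Myo5-end3C-GFP (mean_s, sd_s)
DELAY_MYO5_END3C = (12.6, 4.9)
#: static cortical patch fraction in sla1W41AW108A pan1dPRD cells
STATIC_FRACTION_DOUBLE_MUTANT = 0.981
N_EVENTS_DOUBLE_MUTANT = 216
N_CELLS_DOUBLE_MUTANT = 20


def _child_seed(seed: int, *key: int) -> int:
    state = np.random.SeedSequence([int(seed), *key]).generate_state(1)[0]
    return int(state) & 0x7FFFFFFF


@dataclass
class RecoveryResult:
    value: float
    n: int
    sd: float = float("nan")
    truth: float = float("nan")


def lifetime_recovery(seed: int, lifetime_mean_s: float, lifetime_sd_s: float,
                      n_movies: int = 14, events_per_movie: int = 8,
                      exp_id: int = 1) -> RecoveryResult:
    """Full detection -> linking -> exclusion -> lifetime measurement on
    >= 100 simulated cortical events; returns the mean measured lifetime."""
    n_frames = max(120, int(lifetime_mean_s * 2.5 + 60))
    measured, truths = [], []
    for i in range(n_movies):
        params = SimParams(n_events=events_per_movie, n_frames=n_frames,
                           lifetime_mean_s=lifetime_mean_s,
                           lifetime_sd_s=lifetime_sd_s,
                           seed=_child_seed(seed, exp_id, i))
        movie, truth = simulate_movie(params)
        res = analyze_movie(movie, classify=False)
        measured += res.lifetimes_s
        truths += [t.true_lifetime_s for t in truth]
    arr = np.asarray(measured)
    return RecoveryResult(value=float(arr.mean()), n=len(arr),
                          sd=float(arr.std(ddof=1)),
                          truth=float(np.mean(truths)))


def onset_fraction_recovery(seed: int, fraction_range=(0.70, 0.80),
                            n_movies: int = 7, events_per_movie: int = 8
                            ) -> RecoveryResult:
    """Hidden per-event coupling fraction drawn inside ``fraction_range``;
    returns the recovered cohort mean onset fraction in percent."""
    movies = []
    for i in range(n_movies):
        params = SimParams(n_events=events_per_movie, n_frames=120,
                           threshold_fraction_range=tuple(fraction_range),
                           seed=_child_seed(seed, 4, i))
        movies.append(simulate_movie(params)[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cohort = analyze_cohort(movies, classify=False)
    n = len([p for p in cohort.pairs if p.onset_fraction is not None])
    return RecoveryResult(value=100.0 * cohort.onset_fraction_mean, n=n,
                          sd=100.0 * cohort.onset_fraction_sd,
                          truth=100.0 * float(np.mean(fraction_range)))


def t1_t2_experiment(seed: int, n_movies: int = 7, events_per_movie: int = 8):
    """Switch-coupling check: onset locked to a common intensity level
    (fixed fraction of max with equal amplitudes), rise times variable.

    Returns (T1T2Result, shuffled_r_squared).
    """
    movies = []
    for i in range(n_movies):
        params = SimParams(n_events=events_per_movie, n_frames=150,
                           amplitude_cv=0.0, lifetime_mean_s=35.0,
                           lifetime_sd_s=12.0, lifetime_min_s=8.0,
                           seed=_child_seed(seed, 5, i))
        movies.append(simulate_movie(params)[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cohort = analyze_cohort(movies, classify=False)
    pairs = [p for p in cohort.pairs
             if p.T1_rel_s is not None and p.T2_rel_s is not None]
    t1 = np.array([p.T1_rel_s for p in pairs])
    t2 = np.array([p.T2_rel_s for p in pairs])
    rng = np.random.default_rng(_child_seed(seed, 5, 999))
    shuffled = sps.linregress(t1, rng.permutation(t2)).rvalue ** 2
    return cohort.t1t2, float(shuffled)


def motility_recovery(seed: int,
                      n_events: int = N_EVENTS_DOUBLE_MUTANT,
                      n_cells: int = N_CELLS_DOUBLE_MUTANT,
                      static_fraction: float = STATIC_FRACTION_DOUBLE_MUTANT
                      ) -> RecoveryResult:
    """Double-mutant-style condition: ``n_events`` cortical patches over
    ``n_cells`` cells, a ``static_fraction`` of them truly static and the
    remainder drifting slowly along the cortex; returns the classifier's
    static percentage over unexcluded classifiable tracks."""
    base, extra = divmod(n_events, n_cells)
    sizes = [base + 1] * extra + [base] * (n_cells - extra)
    n_motile_total = n_events - int(np.floor(static_fraction * n_events + 0.5))
    motile = [1 if i < n_motile_total else 0 for i in range(n_cells)]
    counts = {}
    for i, (n_ev, n_mot) in enumerate(zip(sizes, motile)):
        params = SimParams(n_events=n_ev, n_frames=100, frame_interval_s=1.8,
                           comet_mode=True,
                           static_fraction=(n_ev - n_mot) / n_ev,
                           lifetime_mean_s=150.0, lifetime_sd_s=15.0,
                           lifetime_min_s=60.0,
                           seed=_child_seed(seed, 7, i))
        movie, _truth = simulate_comet_condition(params)
        res = analyze_movie(movie)
        for tr in res.green_tracks:
            if tr.excluded_crowded or tr.motility_class is None:
                continue
            counts[tr.motility_class] = counts.get(tr.motility_class, 0) + 1
    total = sum(counts.values())
    pct = round(100.0 * counts.get(STATIC, 0) / total, 1)
    return RecoveryResult(value=pct, n=total,
                          truth=round(100.0 * static_fraction, 1))


def arrival_delay_recovery(seed: int, delay_mean_s: float = DELAY_MYO5_END3C[0],
                           delay_sd_s: float = DELAY_MYO5_END3C[1],
                           n_movies: int = 10, events_per_movie: int = 8
                           ) -> RecoveryResult:
    """Myo5-end3C-like condition: red onset delays drawn from the given
    normal distribution (truncated at 0); returns the mean measured delay."""
    movies, truths = [], []
    for i in range(n_movies):
        params = SimParams(n_events=events_per_movie, n_frames=130,
                           onset_mode="delay", onset_delay_mean_s=delay_mean_s,
                           onset_delay_sd_s=delay_sd_s,
                           lifetime_mean_s=40.0, lifetime_sd_s=8.0,
                           seed=_child_seed(seed, 8, i))
        movie, truth = simulate_movie(params)
        movies.append(movie)
        truths += [(t.red_onset_frame - t.onset_frame) * params.frame_interval_s
                   for t in truth if t.red_onset_frame is not None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cohort = analyze_cohort(movies, classify=False)
    n = len([p for p in cohort.pairs if p.arrival_delay_s is not None])
    return RecoveryResult(value=float(cohort.arrival_delay_mean_s), n=n,
                          sd=float(cohort.arrival_delay_sd_s),
                          truth=float(np.mean(truths)))
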