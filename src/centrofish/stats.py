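"""Statistical layer: Welch t-tests, power-based sample sizing, washout
recovery-onset detection, and the translation-time estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .quantify import QuantRecord

#: Length of the ASPM open reading frame in codons (3477-residue protein).
ASPM_ORF_CODONS = 3477

#: Conventional elongation speed used for the translation-time estimate.
STANDARD_TRANSLATION_RATE_AA_S = 6.0


def two_sample_t(a, b) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) two-sample t-test.

    Returns (t, p).  The degenerate case of zero variance in both samples
    with equal means yields t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def required_n(effect_size: float, alpha: float = 0.05,
               power: float = 0.8, n_max: int = 10_000) -> int:
    """Smallest per-group n for a two-sided two-sample t-test at given power.

    Uses the noncentral-t power function and scans upward from the
    closed-form solution to guarantee the minimal integer n.
    """
    if effect_size <= 0:
        raise ValueError("effect_size must be > 0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    from statsmodels.stats.power import TTestIndPower

    solver = TTestIndPower()
    n_float = solver.solve_power(effect_size=effect_size, alpha=alpha,
                                 power=power, ratio=1.0, alternative="two-sided")
    n = max(2, int(np.floor(n_float)))
    while n <= n_max:
        if solver.power(effect_size=effect_size, nobs1=n, alpha=alpha,
                        ratio=1.0, alternative="two-sided") >= power:
            return n
        n += 1
    raise RuntimeError("no n found below n_max")


def simulated_power(effect_size: float, n: int, alpha: float = 0.05,
                    n_sim: int = 2000, seed: int = 0) -> float:
    """Monte-Carlo power of the Welch test at per-group n (verification aid)."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_sim, n))
    b = rng.normal(effect_size, 1.0, size=(n_sim, n))
    _, p = sps.ttest_ind(a, b, axis=1, equal_var=False)
    return float(np.mean(p < alpha))


@dataclass
class TimeCourse:
    """Quantification records grouped by washout timepoint (hours)."""

    groups: dict[float, list[QuantRecord]]
    channel: str = "rna"

    def validate(self) -> "TimeCourse":
        if 0.0 not in self.groups:
            raise ValueError("TimeCourse must contain a 0-hour group")
        for t, recs in self.groups.items():
            if len(recs) == 0:
                raise ValueError(f"timepoint {t}: empty group")
        return self

    def enrichment_arrays(self) -> dict[float, np.ndarray]:
        return {t: np.array([r.enrichment[self.channel] for r in recs])
                for t, recs in sorted(self.groups.items())}

    @classmethod
    def from_records(cls, records: list[QuantRecord],
                     channel: str = "rna") -> "TimeCourse":
        groups: dict[float, list[QuantRecord]] = {}
        for r in records:
            if r.timepoint is None:
                raise ValueError("record without a timepoint")
            groups.setdefault(float(r.timepoint), []).append(r)
        return cls(groups=groups, channel=channel).validate()


@dataclass
class RecoveryResult:
    """Per-timepoint summary of a washout time-course and the onset call."""

    timepoints: list[float]
    mean: dict[float, float]
    sd: dict[float, float]
    n: dict[float, int]
    t_stat: dict[float, float]
    p_value: dict[float, float]
    onset: float | None
    alpha: float
    channel: str
    recovered_to_baseline: bool | None = None
    baseline_mean: float | None = None

    def to_dict(self) -> dict:
        rows = [
            {"timepoint_h": t, "mean": self.mean[t], "sd": self.sd[t],
             "n": self.n[t],
             "t_vs_0h": self.t_stat.get(t), "p_vs_0h": self.p_value.get(t)}
            for t in self.timepoints
        ]
        return {"channel": self.channel, "alpha": self.alpha,
                "onset_hours": self.onset, "rows": rows,
                "baseline_mean": self.baseline_mean,
                "recovered_to_baseline": self.recovered_to_baseline}


def recovery_onset(tc: TimeCourse, alpha: float = 0.05,
                   baseline_mean: float | None = None,
                   holm: bool = False) -> RecoveryResult:
    """Earliest timepoint whose enrichment significantly exceeds 0 h.

    Each post-0 group is compared to the 0-hour group with a two-sided
    Welch t-test; the onset is the earliest timepoint with p < alpha AND a
    mean above the 0-hour mean (relocalization is directional, so the
    two-sided test is gated on direction).  If ``baseline_mean`` (the
    pre-treatment level) is supplied, the result also reports whether the
    final timepoint's mean remains below it.  ``holm`` applies a Holm
    correction across timepoints (off by default).
    """
    tc.validate()
    arrays = tc.enrichment_arrays()
    timepoints = sorted(arrays)
    ref = arrays[0.0]
    if any(len(arrays[t]) < 2 for t in timepoints):
        raise ValueError("each group needs at least 2 records")

    mean = {t: float(arrays[t].mean()) for t in timepoints}
    sd = {t: float(arrays[t].std(ddof=1)) for t in timepoints}
    n = {t: int(len(arrays[t])) for t in timepoints}

    post = [t for t in timepoints if t > 0.0]
    t_stat, p_value = {}, {}
    for t in post:
        t_stat[t], p_value[t] = two_sample_t(arrays[t], ref)

    p_adj = dict(p_value)
    if holm and post:
        from statsmodels.stats.multitest import multipletests

        _, adj, _, _ = multipletests([p_value[t] for t in post],
                                     alpha=alpha, method="holm")
        p_adj = dict(zip(post, adj))

    onset = None
    for t in post:
        if p_adj[t] < alpha and mean[t] > mean[0.0]:
            onset = t
            break

    recovered = None
    if baseline_mean is not None and post:
        recovered = mean[post[-1]] >= baseline_mean

    return RecoveryResult(timepoints=timepoints, mean=mean, sd=sd, n=n,
                          t_stat=t_stat, p_value=p_value, onset=onset,
                          alpha=alpha, channel=tc.channel,
                          recovered_to_baseline=recovered,
                          baseline_mean=baseline_mean)


def translation_time(orf_codons: int = ASPM_ORF_CODONS,
                     rate: float = STANDARD_TRANSLATION_RATE_AA_S
                     ) -> tuple[float, float]:
    """Minutes to translate an ORF at ``rate`` amino acids per second.

    Returns (minutes, minutes rounded to the nearest 5).  The packaged
    default is the ASPM ORF (3477 codons) at the standard 6 aa/s, which
    takes about 10 minutes.
    """
    if orf_codons < 1:
        raise ValueError("orf_codons must be >= 1")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    minutes = orf_codons / rate / 60.0
    return minutes, float(5 * round(minutes / 5))
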