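"""Supranucleosomal separation-distance domains and rank statistics.

Contact observations are partitioned into consecutive separation windows
(domains I, II, ... — e.g. 35-kb steps up to 250 kb for gene-rich and
gene-poor loci, 25-kb steps up to 150 kb for the gene-desert locus).
Under a statistical-helix organisation, mean contact frequencies alternate
low/high between adjacent domains with genomic period Sh; adjacent domains
are compared with two-sided Mann-Whitney U tests.

Intervals are left-closed right-open ``[a, b)``: a separation equal to a
boundary belongs to the upper domain.  The U test is exact (enumeration)
when the combined sample size is <= 12 with no ties, and uses the normal
approximation with tie and continuity correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DomainScheme",
    "DomainComparison",
    "assign_domains",
    "domain_means",
    "adjacent_domain_tests",
    "star_annotation",
    "mann_whitney",
    "EXACT_MAX_N",
]

_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
          "XI", "XII")

#: combined sample size at or below which the exact U distribution is used
#: (no ties); above it, normal approximation with tie/continuity correction.
EXACT_MAX_N = 12

OUTSIDE = "outside"


@dataclass(frozen=True)
class DomainScheme:
    """Ordered boundaries (kb) of consecutive half-open domains."""

    boundaries: tuple[float, ...]
    scheme_id: str = "custom"

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.boundaries)
        object.__setattr__(self, "boundaries", b)
        if len(b) < 2 or any(x >= y for x, y in zip(b, b[1:])):
            raise ValueError("boundaries must be strictly increasing, >= 2 entries")

    @property
    def labels(self) -> tuple[str, ...]:
        n = len(self.boundaries) - 1
        if n <= len(_ROMAN):
            return _ROMAN[:n]
        return tuple(f"D{i + 1}" for i in range(n))

    @classmethod
    def gene_rich_poor(cls) -> "DomainScheme":
        """35-kb steps from 0 to 250 kb (domains I-VI; last step 45 kb)."""
        return cls((0, 35, 70, 115, 160, 205, 250), "gene_rich_poor")

    @classmethod
    def gene_desert(cls) -> "DomainScheme":
        """25-kb steps from 0 to 150 kb (domains I-VI)."""
        return cls((0, 25, 50, 75, 100, 125, 150), "gene_desert")

    @classmethod
    def from_id(cls, scheme_id: str) -> "DomainScheme":
        if scheme_id == "gene_rich_poor":
            return cls.gene_rich_poor()
        if scheme_id == "gene_desert":
            return cls.gene_desert()
        raise ValueError(f"unknown scheme id {scheme_id!r}")


@dataclass(frozen=True)
class DomainComparison:
    """Mann-Whitney comparison of two adjacent domains."""

    pair: tuple[str, str]
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    u_stat: float
    p_value: float
    stars: str


def _observations(profiles_or_obs):
    """Accept a profile, an iterable of profiles, or raw observations."""
    from .fitting import ContactObservation, ContactProfile

    if isinstance(profiles_or_obs, ContactProfile):
        return list(profiles_or_obs.observations)
    items = list(profiles_or_obs)
    out = []
    for item in items:
        if isinstance(item, ContactProfile):
            out.extend(item.observations)
        elif isinstance(item, ContactObservation):
            out.append(item)
        else:
            raise TypeError(f"cannot interpret {type(item)} as observations")
    return out


def assign_domains(observations, scheme: DomainScheme) -> list[str]:
    """Label each observation with its domain; separations outside every
    interval get the label "outside"."""
    obs = _observations(observations)
    b = scheme.boundaries
    labels = scheme.labels
    out = []
    for o in obs:
        s = o.separation
        if s < b[0] or s >= b[-1]:
            out.append(OUTSIDE)
        else:
            idx = int(np.searchsorted(b, s, side="right")) - 1
            out.append(labels[idx])
    return out


def domain_means(profiles, scheme: DomainScheme) -> pd.DataFrame:
    """Mean pooled contact frequency and count per domain.

    Empty domains are reported with n=0 and NaN mean.
    """
    obs = _observations(profiles)
    labels = assign_domains(obs, scheme)
    by: dict[str, list[float]] = {lab: [] for lab in scheme.labels}
    for o, lab in zip(obs, labels):
        if lab != OUTSIDE:
            by[lab].append(o.frequency)
    rows = [
        {"domain": lab,
         "mean_frequency": float(np.mean(v)) if v else float("nan"),
         "n": len(v)}
        for lab, v in by.items()
    ]
    return pd.DataFrame(rows)


def mann_whitney(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U (statistic of the first sample) and p-value.

    Exact null distribution when n_a + n_b <= EXACT_MAX_N and there are no
    ties; otherwise normal approximation with tie and continuity
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    no_ties = np.unique(combined).size == combined.size
    if np.unique(combined).size == 1:
        return float(a.size * b.size / 2.0), 1.0
    method = "exact" if (a.size + b.size <= EXACT_MAX_N and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def adjacent_domain_tests(profiles, scheme: DomainScheme,
                          alternative: str = "two-sided",
                          convention: str = "fig2") -> list[DomainComparison]:
    """Two-sided Mann-Whitney U test of each pair of adjacent domains.

    Pairs with an empty side are skipped (they do not appear in the
    output); the star annotation follows the requested convention.
    """
    obs = _observations(profiles)
    labels = assign_domains(obs, scheme)
    by: dict[str, list[float]] = {lab: [] for lab in scheme.labels}
    for o, lab in zip(obs, labels):
        if lab != OUTSIDE:
            by[lab].append(o.frequency)
    out = []
    doms = scheme.labels
    for lab_a, lab_b in zip(doms, doms[1:]):
        va, vb = by[lab_a], by[lab_b]
        if not va or not vb:
            continue
        u, p = mann_whitney(va, vb, alternative=alternative)
        out.append(DomainComparison(
            pair=(lab_a, lab_b),
            mean_a=float(np.mean(va)), mean_b=float(np.mean(vb)),
            n_a=len(va), n_b=len(vb),
            u_stat=u, p_value=p,
            stars=star_annotation(p, convention),
        ))
    return out


def star_annotation(p: float, convention: str = "fig2") -> str:
    """Significance stars.

    convention="fig2": "***" for p < 0.01, "**" for p < 0.05, else "".
    convention="fig4": "***" for p < 0.001, "**" for p < 0.01, "*" for
    p < 0.05, else "".
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value must lie in [0, 1], got {p}")
    if convention == "fig2":
        if p < 0.01:
            return "***"
        if p < 0.05:
            return "**"
        return ""
    if convention == "fig4":
        if p < 0.001:
            return "***"
        if p < 0.01:
            return "**"
        if p < 0.05:
            return "*"
        return ""
    raise ValueError(f"unknown star convention {convention!r}")


def comparisons_table(comparisons) -> pd.DataFrame:
    rows = [
        {"domain_a": c.pair[0], "domain_b": c.pair[1],
         "mean_a": c.mean_a, "mean_b": c.mean_b,
         "n_a": c.n_a, "n_b": c.n_b,
         "u": c.u_stat, "p_value": c.p_value, "stars": c.stars}
        for c in comparisons
    ]
    return pd.DataFrame(rows)
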