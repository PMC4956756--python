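"""Overlap statistics and the permutation test of spatial segregation.

Two overlap measures between group-level utilization distributions:

* UDOI, the utilization-distribution overlap index: the product-density
  integral scaled by the area of joint support,
  ``UDOI = A12 * sum_i u1_i u2_i * cell_area`` with
  ``A12 = cell_area * #{cells where both densities > 0}``.  It is 0 for
  disjoint supports, exactly 1 for identical uniform distributions, and can
  exceed 1 when two concentrated distributions co-occur.  The "> 0" support is
  well defined because kernels are hard-truncated at 3 sigma.
* PHR, the home-range overlap: the fraction of one UD's mass falling inside
  the other's isopleth region (50% and 90% levels), reported in both
  directions and as their mean.

Whether observed segregation exceeds chance is judged by a randomization
test: individual UDs are cached, group labels are reshuffled preserving group
sizes, group UDs rebuilt by equal-weight merging, and the overlap recomputed.
The P-value is the proportion of randomized overlaps *smaller* than the
observed one, so small P means the groups overlap unusually little — i.e.
spatial segregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spaceuse import IsoplethRegion, UtilizationDistribution, isopleth, merge_individuals


def udoi(ud1: UtilizationDistribution, ud2: UtilizationDistribution) -> float:
    """Utilization distribution overlap index of two UDs on one grid."""
    if ud1.grid != ud2.grid:
        raise ValueError("UDs must share a grid")
    area = ud1.grid.cell_area_km2
    u1, u2 = ud1.density, ud2.density
    joint = (u1 > 0) & (u2 > 0)
    a12 = area * int(joint.sum())
    return float(a12 * np.sum(u1 * u2) * area)


def phr(ud_from: UtilizationDistribution, region: IsoplethRegion) -> float:
    """Proportion of ``ud_from``'s mass inside an isopleth region."""
    if ud_from.grid != region.grid:
        raise ValueError("UD and region must share a grid")
    return float(ud_from.density[region.mask].sum() * ud_from.grid.cell_area_km2)


@dataclass
class OverlapResult:
    udoi: float
    phr_levels: dict  # level -> {"a_in_b": , "b_in_a": , "mean": }


def overlap(
    ud_a: UtilizationDistribution,
    ud_b: UtilizationDistribution,
    levels: tuple[float, ...] = (0.5, 0.9),
) -> OverlapResult:
    """UDOI plus directed and symmetrized PHR at the given isopleth levels."""
    out = {}
    for level in levels:
        a_in_b = phr(ud_a, isopleth(ud_b, level))
        b_in_a = phr(ud_b, isopleth(ud_a, level))
        out[level] = {"a_in_b": a_in_b, "b_in_a": b_in_a, "mean": 0.5 * (a_in_b + b_in_a)}
    return OverlapResult(udoi=udoi(ud_a, ud_b), phr_levels=out)


@dataclass
class RandomizationResult:
    observed: float
    null: np.ndarray
    pvalue: float
    n_permutations: int
    seed: int
    statistic: str
    group_sizes: tuple[int, int]

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null, ddof=1))

    @property
    def pvalue_label(self) -> str:
        """Table-style label: '< 1/N' when no null draw falls below the observed."""
        if self.pvalue == 0.0:
            return f"<{1.0 / self.n_permutations:g}"
        return f"{self.pvalue:g}"

    def summary(self) -> dict:
        return {
            "statistic": self.statistic,
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "pvalue": self.pvalue,
            "pvalue_label": self.pvalue_label,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def _group_overlap_stack(
    stack: np.ndarray,
    members_a: np.ndarray,
    members_b: np.ndarray,
    area: float,
    statistic: str,
    level: float | None,
) -> np.ndarray:
    """Overlap statistic for one or many label assignments.

    ``members_a``/``members_b`` are boolean matrices (n_assignments, k); the
    group UD of an assignment is the mean of its members' normalized densities
    (each row of ``stack`` integrates to 1, so the mean does as well).
    """
    ga = members_a.astype(float) @ stack / members_a.sum(axis=1, keepdims=True)
    gb = members_b.astype(float) @ stack / members_b.sum(axis=1, keepdims=True)
    if statistic == "udoi":
        a12 = area * ((ga > 0) & (gb > 0)).sum(axis=1)
        return a12 * (ga * gb).sum(axis=1) * area
    if statistic == "phr":
        # symmetrized PHR at `level`: mean of directed mass fractions
        out = np.empty(ga.shape[0])
        for i in range(ga.shape[0]):
            ra = _isopleth_mask_flat(ga[i], area, level)
            rb = _isopleth_mask_flat(gb[i], area, level)
            out[i] = 0.5 * (ga[i][rb].sum() + gb[i][ra].sum()) * area
        return out
    raise ValueError(f"unknown statistic {statistic!r}")


def _isopleth_mask_flat(dens: np.ndarray, area: float, level: float) -> np.ndarray:
    order = np.argsort(dens)[::-1]
    mass = np.cumsum(dens[order]) * area
    total = dens.sum() * area
    k = int(np.searchsorted(mass, level * total - 1e-12)) + 1
    k = min(k, dens.size)
    cut = dens[order[k - 1]]
    return dens >= cut if cut > 0 else dens > 0


def randomization_test(
    individual_uds: list[UtilizationDistribution],
    labels: list,
    statistic: str = "udoi",
    level: float = 0.9,
    n_permutations: int = 1000,
    seed: int = 0,
) -> RandomizationResult:
    """Permutation test of spatial segregation between two groups.

    Individuals (not locations) are the exchangeable units: locations within
    an individual are serially dependent, so labels are reshuffled across
    individuals preserving group sizes.  Each permutation rebuilds the two
    group UDs by equal-weight merging of the cached individual UDs and
    recomputes the overlap; P = #{null < observed} / N.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {list(groups)}")
    sizes = [(labels == g).sum() for g in groups]
    if min(sizes) < 2:
        raise ValueError("each group needs at least 2 individuals")
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    g0 = individual_uds[0].grid
    if any(u.grid != g0 for u in individual_uds):
        raise ValueError("all individual UDs must share a grid")

    k = len(individual_uds)
    stack = np.stack([u.normalized().density.ravel() for u in individual_uds])
    area = g0.cell_area_km2
    obs_a = (labels == groups[0])[None, :]
    obs_b = (labels == groups[1])[None, :]
    observed = float(
        _group_overlap_stack(stack, obs_a, obs_b, area, statistic, level)[0]
    )

    rng = np.random.default_rng(seed)
    perm = np.stack([rng.permutation(k) for _ in range(n_permutations)])
    na = int(sizes[0])
    members_a = np.zeros((n_permutations, k), dtype=bool)
    np.put_along_axis(members_a, perm[:, :na], True, axis=1)
    members_b = ~members_a
    null = _group_overlap_stack(stack, members_a, members_b, area, statistic, level)

    pvalue = float(np.sum(null < observed) / n_permutations)
    return RandomizationResult(
        observed=observed,
        null=null,
        pvalue=pvalue,
        n_permutations=n_permutations,
        seed=seed,
        statistic=statistic,
        group_sizes=(int(sizes[0]), int(sizes[1])),
    )


def group_ud(individual_uds: list[UtilizationDistribution], labels, group) -> UtilizationDistribution:
    """Equal-weight merged UD of the individuals carrying ``group`` label."""
    members = [u for u, lab in zip(individual_uds, labels) if lab == group]
    if not members:
        raise ValueError(f"no individuals with label {group!r}")
    return merge_individuals(members)
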