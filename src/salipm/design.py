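"""Survey-design metadata: occasion timings per site on the half-month grid."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SurveyDesign", "default_study_design"]

_GRID_TOL = 1e-9


def _on_half_month_grid(t: np.ndarray) -> bool:
    return bool(np.all(np.abs(t / 0.5 - np.round(t / 0.5)) <= _GRID_TOL))


@dataclass
class SurveyDesign:
    """Occasion timings and cohort settings for a multi-site two-season study.

    Parameters
    ----------
    occasion_times : dict
        Site label -> strictly increasing month offsets (multiples of 0.5)
        of the capture occasions, from the start of the study.
    season_break : dict
        Site label -> index of the first occasion belonging to season 2.
    n_initial : dict
        Site label -> latent cohort size seeded into the simulation.
    juvenile_fraction : float
        Mixture weight of the juvenile component in the initial size
        distribution (juveniles ~ Normal(25, 2), adults ~ Normal(40, 16)).
    staggered_entry : float
        Fraction of the cohort whose availability starts at a uniformly
        drawn later season-1 occasion instead of occasion 0.
    """

    occasion_times: dict[str, np.ndarray]
    season_break: dict[str, int]
    n_initial: dict[str, int] = field(default_factory=dict)
    juvenile_fraction: float = 0.25
    staggered_entry: float = 0.0

    def __post_init__(self) -> None:
        self.occasion_times = {
            s: np.asarray(t, dtype=float) for s, t in self.occasion_times.items()
        }
        for site, t in self.occasion_times.items():
            if t.ndim != 1 or len(t) < 4:
                raise ValueError(f"{site}: need at least 4 occasions")
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"{site}: occasion times must be strictly increasing")
            if not _on_half_month_grid(t):
                raise ValueError(f"{site}: occasion times must be multiples of 0.5 month")
            k = self.season_break.get(site)
            if k is None or not (2 <= k <= len(t) - 2):
                raise ValueError(f"{site}: season break must leave >=2 occasions per season")
        if not self.n_initial:
            self.n_initial = {s: 475 for s in self.occasion_times}

    @property
    def sites(self) -> list[str]:
        return list(self.occasion_times)

    def season_of_occasion(self, site: str) -> np.ndarray:
        """Season label (1 or 2) of each occasion at ``site``."""
        t = self.occasion_times[site]
        k = self.season_break[site]
        return np.where(np.arange(len(t)) < k, 1, 2)

    def intervals(self, site: str) -> np.ndarray:
        """Month lengths of the inter-occasion intervals at ``site``."""
        return np.diff(self.occasion_times[site])


def default_study_design(n_per_site: int = 475,
                         staggered_entry: float = 0.0) -> SurveyDesign:
    """The study layout: 3 sites; 6 season-1 occasions each; 7, 7, and 8
    season-2 occasions; occasions roughly monthly with the occasional
    1.5/2.5-month gap; a ~6-month summer break between seasons.
    """
    occ = {
        "site1": [0.0, 1.0, 2.5, 3.5, 4.5, 5.5,
                  12.0, 13.0, 14.0, 15.0, 16.0, 17.0, 18.0],
        "site2": [0.0, 1.0, 3.5, 4.5, 5.5, 6.5,
                  12.0, 13.0, 14.0, 15.0, 16.0, 17.0, 18.0],
        "site3": [0.0, 1.0, 3.5, 4.5, 5.5, 6.5,
                  12.0, 13.0, 14.0, 15.0, 16.0, 17.0, 18.0, 19.0],
    }
    brk = {"site1": 6, "site2": 6, "site3": 6}
    return SurveyDesign(
        occasion_times=occ,
        season_break=brk,
        n_initial={s: n_per_site for s in occ},
        staggered_entry=staggered_entry,
    )
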