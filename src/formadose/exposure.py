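"""Inhalation exposure schedules.

Exposures are square waves: ordered, non-overlapping episodes of constant
inhaled concentration with instantaneous on/off (no chamber ramp). Times are
hours. The repeated daily-exposure builder places exposure day ``n`` (1-based)
at ``[24*n, 24*n + hours)`` so that t = 0 sits one day before the first
exposure; with that origin the published sampling times of the 28-day protocol
are reproduced exactly (e.g. day-7 sampling one hour after a 6-h exposure
falls at 24*7 + 7 = 175 h). The chronic 12-week protocol and single exposures
start at t = 0, which reproduces their published sampling times (1947 h and
7 h respectively).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


@dataclass(frozen=True)
class Episode:
    start_h: float
    end_h: float
    ppm: float

    def __post_init__(self) -> None:
        if self.end_h <= self.start_h:
            raise ValueError(f"episode end {self.end_h} must exceed start {self.start_h}")
        if self.ppm < 0:
            raise ValueError("episode ppm must be non-negative")


@dataclass(frozen=True)
class ExposureSchedule:
    """An ordered set of exposure episodes plus the times at which tissue is sampled."""

    label: str
    episodes: tuple[Episode, ...]
    horizon_h: float
    sampling_times: tuple[float, ...]

    def __post_init__(self) -> None:
        prev_end = -float("inf")
        for ep in self.episodes:
            if ep.start_h < prev_end:
                raise ValueError("episodes must be ordered and non-overlapping")
            prev_end = ep.end_h
        if self.episodes and self.episodes[-1].end_h > self.horizon_h:
            raise ValueError("episodes extend beyond the schedule horizon")
        for t in self.sampling_times:
            if not 0 <= t <= self.horizon_h:
                raise ValueError(f"sampling time {t} outside horizon {self.horizon_h}")
        if any(b <= a for a, b in zip(self.sampling_times, self.sampling_times[1:])):
            raise ValueError("sampling times must be strictly increasing")

    @property
    def total_exposed_hours(self) -> float:
        return sum(ep.end_h - ep.start_h for ep in self.episodes)

    @property
    def max_ppm(self) -> float:
        return max((ep.ppm for ep in self.episodes), default=0.0)

    def breakpoints(self) -> list[float]:
        """Episode on/off edges within [0, horizon] — integration restart points."""
        edges = {0.0, float(self.horizon_h)}
        for ep in self.episodes:
            edges.add(float(ep.start_h))
            edges.add(float(ep.end_h))
        return sorted(t for t in edges if 0.0 <= t <= self.horizon_h)

    def to_table(self, path: str | Path) -> None:
        """Serialize episodes as delimited text (start_h, end_h, ppm) plus sampling times."""
        lines = ["start_h\tend_h\tppm"]
        lines += [f"{ep.start_h!r}\t{ep.end_h!r}\t{ep.ppm!r}" for ep in self.episodes]
        lines.append("# sampling_times\t" + ",".join(repr(t) for t in self.sampling_times))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_table(cls, path: str | Path, label: str | None = None) -> "ExposureSchedule":
        path = Path(path)
        episodes: list[Episode] = []
        sampling: tuple[float, ...] = ()
        for line in path.read_text().splitlines():
            if line.startswith("# sampling_times"):
                _, _, raw = line.partition("\t")
                sampling = tuple(float(x) for x in raw.split(",") if x.strip())
            elif line and not line.startswith(("start_h", "#")):
                s, e, p = (float(x) for x in line.split("\t"))
                episodes.append(Episode(s, e, p))
        horizon = max(
            [ep.end_h for ep in episodes] + [max(sampling, default=0.0)], default=0.0
        )
        return cls(label or path.stem, tuple(episodes), horizon, sampling)


def ppm_at(schedule: ExposureSchedule, t: float) -> float:
    """Instantaneous inhaled concentration at time ``t`` (intervals are [start, end))."""
    if not 0 <= t <= schedule.horizon_h:
        raise ValueError(f"t={t} outside schedule horizon [0, {schedule.horizon_h}]")
    for ep in schedule.episodes:
        if ep.start_h <= t < ep.end_h:
            return ep.ppm
    return 0.0


def single_exposure(
    ppm: float, duration_h: float = 6.0, sample_at_h: float = 7.0, label: str | None = None
) -> ExposureSchedule:
    """One exposure of ``duration_h`` starting at t = 0, sampled at ``sample_at_h``.

    Defaults realise the single-6-h-exposure protocol with sacrifice one hour
    post-exposure (7 h from the start of exposure).
    """
    if ppm < 0:
        raise ValueError("ppm must be non-negative")
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    horizon = max(duration_h, sample_at_h)
    episodes = (Episode(0.0, duration_h, ppm),) if ppm > 0 else ()
    return ExposureSchedule(
        label or f"single_{ppm}ppm", episodes, horizon, (sample_at_h,)
    )


def daily_schedule(
    ppm: float,
    n_exposure_days: int,
    hours_per_day: float = 6.0,
    first_start_h: float = 24.0,
    sample_days: Sequence[int] = (),
    sample_offset_h: float = 7.0,
    post_samples_h: Sequence[float] = (),
    label: str | None = None,
) -> ExposureSchedule:
    """Consecutive daily exposures: day ``n`` occupies [24*n, 24*n + hours_per_day).

    ``sample_days`` are 1-based exposure days sampled ``sample_offset_h`` hours
    after that day's exposure start; ``post_samples_h`` are offsets from the end
    of the last episode. With the defaults the 28-day 2-ppm protocol samples at
    weeks 1-4 give 175, 343, 511, 679 h and the post-exposure offsets
    6/24/72/168 h give 684, 702, 750, 846 h.
    """
    if ppm < 0:
        raise ValueError("ppm must be non-negative")
    if n_exposure_days < 1:
        raise ValueError("need at least one exposure day")
    if hours_per_day <= 0 or hours_per_day > 24:
        raise ValueError("hours_per_day must lie in (0, 24]")
    day_starts = [first_start_h + 24.0 * (n - 1) for n in range(1, n_exposure_days + 1)]
    episodes = tuple(
        Episode(s, s + hours_per_day, ppm) for s in day_starts
    ) if ppm > 0 else ()
    last_end = day_starts[-1] + hours_per_day
    samples = sorted(
        {day_starts[d - 1] + sample_offset_h for d in sample_days}
        | {last_end + off for off in post_samples_h}
    )
    if not samples:
        samples = [last_end + 1.0]
    horizon = max(last_end, samples[-1])
    return ExposureSchedule(
        label or f"daily_{n_exposure_days}d_{ppm}ppm",
        episodes,
        horizon,
        tuple(samples),
    )


def casanova_schedule(ppm: float, label: str | None = None) -> ExposureSchedule:
    """The chronic DPX protocol: 6 h/day, 5 days/week for 11 weeks and 4 days,
    then a final 3-h exposure on the 5th day of the 12th week with sacrifice
    immediately after (sampling time 1947 h).

    Calendar day ``d`` (1-based) starts at 24*(d-1) — the published sampling
    time of this protocol is counted from the start of the first exposure, so
    t = 0 is the first exposure onset. Day ``d`` is an exposure day when its
    weekday index ``(d-1) % 7`` is 0-4; days 1-81 carry 6-h episodes (59 of
    them) and day 82, the 5th day of the 12th week, the final 3-h episode
    [1944, 1947).
    """
    if ppm < 0:
        raise ValueError("ppm must be non-negative")
    episodes: list[Episode] = []
    for d in range(1, 82):
        if (d - 1) % 7 < 5:  # 5 exposure days per 7-day week
            start = 24.0 * (d - 1)
            episodes.append(Episode(start, start + 6.0, ppm))
    final_start = 24.0 * 81.0  # day 82 episode begins at 1944 h
    episodes.append(Episode(final_start, final_start + 3.0, ppm))
    sample = final_start + 3.0  # 1947 h, sacrifice immediately post-exposure
    eps = tuple(episodes) if ppm > 0 else ()
    return ExposureSchedule(label or f"casanova_{ppm}ppm", eps, sample, (sample,))


def leng_schedule(ppm: float = 0.3, label: str | None = None) -> ExposureSchedule:
    """The low-dose DG protocol: 6 h/day for 28 consecutive days, adducts
    collected 672 h (28 days) from the start of the first exposure."""
    if ppm < 0:
        raise ValueError("ppm must be non-negative")
    episodes = tuple(
        Episode(24.0 * (d - 1), 24.0 * (d - 1) + 6.0, ppm) for d in range(1, 29)
    ) if ppm > 0 else ()
    return ExposureSchedule(label or f"leng_{ppm}ppm", episodes, 672.0, (672.0,))


PROTOCOLS = {
    "single": single_exposure,
    "daily": lambda ppm, **kw: daily_schedule(
        ppm,
        n_exposure_days=int(kw.pop("n_exposure_days", 28)),
        sample_days=kw.pop("sample_days", (7, 14, 21, 28)),
        post_samples_h=kw.pop("post_samples_h", (6.0, 24.0, 72.0, 168.0)),
        **kw,
    ),
    "casanova": casanova_schedule,
    "leng": leng_schedule,
}
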