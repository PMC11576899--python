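"""Three-ancestry admixture demography for the simulator.

The default model mirrors the broad-brush demographic history of Britain:
a single ancestral population from which a hunter-gatherer-like branch
(WHG) splits first; the remaining lineage later splits into farmer-like
(EEF) and steppe-like (SBA) branches. The present-day lineage starts as the
WHG branch and receives two admixture pulses — a large farmer pulse, then a
steppe pulse — with default proportions chosen so the expected final WHG
contribution is 12%.

All times are in generations before present; pulse proportions are the
fraction of the receiving lineage's parents drawn from the source at that
generation, so expected final ancestry fractions follow in closed form by
multiplying the surviving fractions of successive pulses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

ANCESTRIES = ("WHG", "EEF", "SBA")


@dataclass(frozen=True)
class Pulse:
    time: int  # generations ago
    source: str
    proportion: float


@dataclass(frozen=True)
class DemographyModel:
    """Validated admixture demography with closed-form ancestry expectations."""

    ne_ancestral: int = 10_000
    ne_branch: dict = field(
        default_factory=lambda: {"WHG": 10_000, "EEF": 10_000, "SBA": 10_000}
    )
    ne_present: int = 10_000
    t_deep_split: int = 800  # WHG vs (EEF,SBA) ancestor
    t_farmer_steppe_split: int = 500  # EEF vs SBA
    base_ancestry: str = "WHG"
    pulses: tuple[Pulse, ...] = (
        Pulse(time=200, source="EEF", proportion=0.75),
        Pulse(time=150, source="SBA", proportion=0.52),
    )

    def __post_init__(self) -> None:
        for p in self.pulses:
            if not 0.0 <= p.proportion <= 1.0:
                raise ValueError(f"pulse proportion {p.proportion} outside [0, 1]")
            if p.source not in ANCESTRIES:
                raise ValueError(f"unknown pulse source {p.source!r}")
        times = [self.t_deep_split, self.t_farmer_steppe_split] + [
            p.time for p in self.pulses
        ]
        if any(t <= 0 for t in times):
            raise ValueError("event times must be positive (generations ago)")
        if not all(a > b for a, b in zip(times, times[1:])):
            raise ValueError("event times must be strictly decreasing: "
                             "deep split > farmer/steppe split > pulses")
        for ne in (self.ne_ancestral, self.ne_present, *self.ne_branch.values()):
            if ne <= 0:
                raise ValueError("population sizes must be positive")

    def expected_ancestry_fractions(self) -> dict[str, float]:
        """Expected final ancestry composition of the present-day lineage."""
        comp = {a: 0.0 for a in ANCESTRIES}
        comp[self.base_ancestry] = 1.0
        for p in sorted(self.pulses, key=lambda p: -p.time):
            for a in comp:
                comp[a] *= 1.0 - p.proportion
            comp[p.source] += p.proportion
        return comp

    def scaled(self, factor: int) -> "DemographyModel":
        """Rescaled copy: Ne and times divided by ``factor``."""
        return replace(
            self,
            ne_ancestral=max(2, self.ne_ancestral // factor),
            ne_branch={k: max(2, v // factor) for k, v in self.ne_branch.items()},
            ne_present=max(2, self.ne_present // factor),
            t_deep_split=max(3, self.t_deep_split // factor),
            t_farmer_steppe_split=max(2, self.t_farmer_steppe_split // factor),
            pulses=tuple(
                replace(p, time=max(1, p.time // factor)) for p in self.pulses
            ),
        )


def build_demography(
    ne_ancestral: int = 10_000,
    ne_branch: dict | None = None,
    ne_present: int = 10_000,
    t_deep_split: int = 800,
    t_farmer_steppe_split: int = 500,
    pulses: list[tuple[int, str, float]] | None = None,
    base_ancestry: str = "WHG",
) -> DemographyModel:
    """Build and validate a :class:`DemographyModel` from plain config values."""
    kwargs = dict(
        ne_ancestral=ne_ancestral,
        ne_present=ne_present,
        t_deep_split=t_deep_split,
        t_farmer_steppe_split=t_farmer_steppe_split,
        base_ancestry=base_ancestry,
    )
    if ne_branch is not None:
        kwargs["ne_branch"] = dict(ne_branch)
    if pulses is not None:
        kwargs["pulses"] = tuple(Pulse(t, s, m) for t, s, m in pulses)
    return DemographyModel(**kwargs)
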