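"""Chemical-shift library of urinary metabolites.

Each entry maps a metabolite to the ppm positions of its resonances (one
peak per listed shift; J-coupling fine structure is below the bin width and
not modelled) together with a metabolic-pathway label.  The packaged library
covers the creatinine reference resonance (methyl singlet at 3.05 ppm) plus
the fifteen heat-stress candidate biomarkers, so the whole discovery
pipeline runs offline and reproducibly; live HMDB/KEGG queries are out of
scope by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .exceptions import ConfigurationError

__all__ = [
    "MetaboliteEntry",
    "MetaboliteLibrary",
    "default_library",
    "default_effects",
    "read_library",
    "write_library",
]


@dataclass(frozen=True)
class MetaboliteEntry:
    name: str
    pathway: str
    shifts: tuple[float, ...]
    relative_amplitudes: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.shifts) == 0:
            raise ConfigurationError(f"{self.name}: no chemical shifts")
        if len(self.relative_amplitudes) != len(self.shifts):
            raise ConfigurationError(
                f"{self.name}: {len(self.shifts)} shifts but "
                f"{len(self.relative_amplitudes)} relative amplitudes"
            )
        if any(a <= 0 for a in self.relative_amplitudes):
            raise ConfigurationError(f"{self.name}: amplitudes must be positive")


@dataclass
class MetaboliteLibrary:
    entries: list[MetaboliteEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConfigurationError(f"duplicate metabolite names: {dupes}")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def get(self, name: str) -> MetaboliteEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def shifts(self, name: str) -> tuple[float, ...]:
        return self.get(name).shifts

    def iter_peaks(self):
        """Yield (entry, shift, relative_amplitude) for every resonance."""
        for e in self.entries:
            for s, a in zip(e.shifts, e.relative_amplitudes):
                yield e, s, a

    def check_range(self, ppm_range: tuple[float, float]) -> None:
        lo, hi = sorted(ppm_range)
        for e in self.entries:
            for s in e.shifts:
                if not (lo <= s <= hi):
                    raise ConfigurationError(
                        f"{e.name}: shift {s} ppm outside range {lo}..{hi}"
                    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metabolite": [e.name for e in self.entries],
                "pathway": [e.pathway for e in self.entries],
                "shifts_ppm": [",".join(f"{s:g}" for s in e.shifts) for e in self.entries],
                "relative_amplitudes": [
                    ",".join(f"{a:g}" for a in e.relative_amplitudes)
                    for e in self.entries
                ],
            }
        )


def write_library(lib: MetaboliteLibrary, path: str | Path) -> None:
    lib.to_frame().to_csv(path, sep="\t", index=False)


def read_library(path) -> MetaboliteLibrary:
    df = pd.read_csv(path, sep="\t")
    entries = [
        MetaboliteEntry(
            name=row.metabolite,
            pathway=row.pathway,
            shifts=tuple(float(x) for x in str(row.shifts_ppm).split(",")),
            relative_amplitudes=tuple(
                float(x) for x in str(row.relative_amplitudes).split(",")
            ),
        )
        for row in df.itertuples()
    ]
    return MetaboliteLibrary(entries)


def default_library() -> MetaboliteLibrary:
    """The packaged library: creatinine plus the 15 candidate biomarkers."""
    with resources.as_file(
        resources.files("nmrstress.data") / "metabolite_library.tsv"
    ) as p:
        return read_library(p)


#: Treatment effects observed in the heat-stress study, expressed as HS/TN
#: concentration ratios.  Under-excreted metabolites (reported with negative
#: signed-ratio fold changes) appear here as reciprocals, e.g. a signed fold
#: change of -2.64 becomes a ratio of 1/2.64.
DEFAULT_FOLD_CHANGES: dict[str, float] = {
    "Hippurate": 2.74,
    "OH-Phenylacetylglycine": 2.16,
    "Trimethylamine N-oxide": 2.11,
    "3-Methyladenine": 1.82,
    "Phosphocreatine": 1.69,
    "Phenylglyoxylate": 1.59,
    "OH-Phenylacetate": 1.51,
    "Allantoic acid": 1 / 1.52,
    "Cholecalciferol": 1 / 1.57,
    "Glycogen": 1 / 1.66,
    "Galactitol": 1 / 1.81,
    "6OH-Dopamine": 1 / 1.87,
    "Pyridoxal": 1 / 2.03,
    "β-Alanine": 1 / 2.09,
    "Histamine": 1 / 2.64,
}


def default_effects() -> dict[str, float]:
    """HS/TN fold-change map used as the generator's ground truth."""
    return dict(DEFAULT_FOLD_CHANGES)
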