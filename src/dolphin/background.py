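"""Background (expected) amino-acid frequencies.

The expected frequency f_l of each letter l is the frequency at which it
occurs in a large reference protein collection; the package ships the
UniProtKB/Swiss-Prot composition table and accepts any user-supplied
20-letter table in the same two-column TSV layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .alphabet import AMINO_ACIDS
from .errors import BackgroundError

_SUM_REJECT_TOL = 1e-3
_SUM_OK_TOL = 1e-6


@dataclass(frozen=True)
class BackgroundFrequencies:
    """Expected frequency of each of the 20 amino acids.

    Parameters
    ----------
    frequencies
        Mapping letter -> expected frequency. Must cover exactly the 20
        standard letters, with every value positive. Sums within 1e-3 of
        1 are renormalized; anything further off is rejected.
    source
        Free-text provenance label; matrices remember which background
        they were built against and refuse to mix two labels.
    """

    frequencies: dict[str, float]
    source: str = "unspecified"
    _vector: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.frequencies)
        extra = set(self.frequencies) - set(AMINO_ACIDS)
        if missing or extra:
            raise BackgroundError(
                f"background table must cover exactly the 20 amino acids; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        vec = np.array([self.frequencies[aa] for aa in AMINO_ACIDS], dtype=float)
        if np.any(vec <= 0):
            bad = [aa for aa in AMINO_ACIDS if self.frequencies[aa] <= 0]
            raise BackgroundError(f"non-positive background frequency for {bad}")
        total = float(vec.sum())
        if abs(total - 1.0) > _SUM_REJECT_TOL:
            raise BackgroundError(
                f"background frequencies sum to {total:.6f}; "
                f"more than {_SUM_REJECT_TOL} away from 1"
            )
        if abs(total - 1.0) > _SUM_OK_TOL:
            vec = vec / total
            object.__setattr__(
                self, "frequencies", {aa: float(v) for aa, v in zip(AMINO_ACIDS, vec)}
            )
        object.__setattr__(self, "_vector", vec)

    def __getitem__(self, letter: str) -> float:
        return self.frequencies[letter]

    def as_vector(self) -> np.ndarray:
        """Frequencies as a length-20 array in AMINO_ACIDS order."""
        return self._vector.copy()


def read_background(path: str | Path, source: str | None = None) -> BackgroundFrequencies:
    """Read a two-column ``letter<TAB>value`` TSV ('#' lines ignored).

    Values may be fractions or percentages; percentages (sum near 100)
    are divided by 100 before the sum-to-one check.
    """
    path = Path(path)
    freqs: dict[str, float] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise BackgroundError(f"malformed background line: {line!r}")
        letter, value = parts[0].strip().upper(), float(parts[1])
        freqs[letter] = value
    total = sum(freqs.values())
    if abs(total - 100.0) < 100.0 * _SUM_REJECT_TOL:
        freqs = {k: v / 100.0 for k, v in freqs.items()}
    return BackgroundFrequencies(freqs, source=source or path.stem)


def swissprot_background() -> BackgroundFrequencies:
    """The pinned UniProtKB/Swiss-Prot composition shipped with the package."""
    ref = resources.files("dolphin.data") / "background_swissprot.tsv"
    with resources.as_file(ref) as path:
        return read_background(path, source="swissprot")
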