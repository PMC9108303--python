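"""Population and habitat containers plus spatial queries.

Agents live in one of two regions of 5000 square patches each: a
freshwater river (a 100 x 50 grid with plain Euclidean distance — no
wrap-around) and a marine region.  Freshwater coordinates matter because
mate search and the sneaker decision are radius-based; the marine region
is only ever sampled as "which patch did this migrant land on" so no
coordinates are stored for fish at sea.

The :class:`Population` is a struct-of-arrays: one NumPy column per agent
attribute plus a ``(n, 20, 2)`` genome block, with an ``alive`` mask so
that weekly mortality never has to rebuild every array.  Dead rows are
reclaimed once a year via :meth:`Population.compact`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetics import N_LOCI

FRESHWATER = 0
MARINE = 1

RESIDENT = 0
ANADROMOUS = 1

#: each region is a GRID_WIDTH x GRID_HEIGHT grid of square patches
GRID_WIDTH = 100
GRID_HEIGHT = 50
PATCHES_PER_REGION = GRID_WIDTH * GRID_HEIGHT  # 5000


@dataclass
class HabitatGrid:
    """Two-region habitat; marine patches carry a fixed sea-lice flag.

    Exactly ``round(prop_parasites * 5000)`` marine patches are flagged
    (sampled without replacement at initialisation and fixed for the
    whole run).
    """

    lice_flags: np.ndarray = field(
        default_factory=lambda: np.zeros(PATCHES_PER_REGION, dtype=bool)
    )

    @classmethod
    def create(cls, prop_parasites: float, rng: np.random.Generator) -> "HabitatGrid":
        if not 0.0 <= prop_parasites <= 1.0:
            raise ValueError(
                f"prop-parasites must be in [0, 1], got {prop_parasites}"
            )
        n_lice = int(round(prop_parasites * PATCHES_PER_REGION))
        flags = np.zeros(PATCHES_PER_REGION, dtype=bool)
        if n_lice:
            flags[rng.choice(PATCHES_PER_REGION, size=n_lice, replace=False)] = True
        return cls(lice_flags=flags)

    @property
    def n_lice_patches(self) -> int:
        return int(self.lice_flags.sum())

    def random_freshwater_patch(
        self, rng: np.random.Generator, n: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Uniform random freshwater coordinates for ``n`` fish."""
        patch = rng.integers(0, PATCHES_PER_REGION, size=n)
        return (patch // GRID_HEIGHT).astype(np.int16), (patch % GRID_HEIGHT).astype(
            np.int16
        )

    def random_marine_patch(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.integers(0, PATCHES_PER_REGION, size=n)


_SCALAR_FIELDS: dict[str, type] = {
    "id": np.int64,
    "sex": np.int8,
    "age_weeks": np.int32,
    "habitat": np.int8,
    "tactic": np.int8,
    "threshold": np.float64,
    "condition": np.float64,
    "quality": np.float64,
    "base_quality": np.float64,
    "parasitised": np.bool_,
    "sneaking": np.bool_,
    "x": np.int16,
    "y": np.int16,
    "weeks_at_sea": np.int32,
    "times_at_sea": np.int32,
}


class Population:
    """Struct-of-arrays container for every trout ever alive this segment.

    Columns (one value per agent): id, sex (0=male, 1=female), age in
    weeks, habitat, tactic, liability threshold, condition, quality (mm),
    base_quality (restore point for the sneaker boost), parasitised,
    sneaking, freshwater x/y, weeks_at_sea (accrual counter for the
    current sojourn), times_at_sea (number of outmigrations).  The genome
    block is ``(n, 20, 2)`` uint8.
    """

    def __init__(self, fields: dict[str, np.ndarray], genomes: np.ndarray):
        n = len(genomes)
        for name, dtype in _SCALAR_FIELDS.items():
            arr = np.asarray(fields[name], dtype=dtype)
            if arr.shape != (n,):
                raise ValueError(f"field {name!r} has shape {arr.shape}, expected ({n},)")
            setattr(self, name, arr)
        self.genomes = np.asarray(genomes, dtype=np.uint8).reshape(n, N_LOCI, 2)
        self.alive = np.ones(n, dtype=bool)
        self._next_id = int(self.id.max()) + 1 if n else 0
        self._alive_idx: np.ndarray | None = None

    # -- bookkeeping ---------------------------------------------------

    @classmethod
    def empty(cls) -> "Population":
        fields = {k: np.empty(0, dtype=v) for k, v in _SCALAR_FIELDS.items()}
        return cls(fields, np.empty((0, N_LOCI, 2), dtype=np.uint8))

    def __len__(self) -> int:
        return len(self.id)

    @property
    def n_alive(self) -> int:
        return len(self.alive_indices)

    @property
    def alive_indices(self) -> np.ndarray:
        if self._alive_idx is None:
            self._alive_idx = np.flatnonzero(self.alive)
        return self._alive_idx

    def kill(self, idx: np.ndarray) -> None:
        self.alive[idx] = False
        self._alive_idx = None

    def append(self, fields: dict[str, np.ndarray], genomes: np.ndarray) -> np.ndarray:
        """Append newborns; ids are assigned here.  Returns their indices."""
        n_new = len(genomes)
        if n_new == 0:
            return np.empty(0, dtype=np.int64)
        new_ids = np.arange(self._next_id, self._next_id + n_new, dtype=np.int64)
        self._next_id += n_new
        fields = dict(fields)
        fields["id"] = new_ids
        start = len(self)
        for name, dtype in _SCALAR_FIELDS.items():
            old = getattr(self, name)
            setattr(self, name, np.concatenate([old, np.asarray(fields[name], dtype=dtype)]))
        self.genomes = np.concatenate(
            [self.genomes, np.asarray(genomes, dtype=np.uint8).reshape(n_new, N_LOCI, 2)]
        )
        self.alive = np.concatenate([self.alive, np.ones(n_new, dtype=bool)])
        self._alive_idx = None
        return np.arange(start, start + n_new, dtype=np.int64)

    def compact(self) -> None:
        """Drop dead rows (called once a year; queries never see them)."""
        keep = self.alive
        for name in _SCALAR_FIELDS:
            setattr(self, name, getattr(self, name)[keep])
        self.genomes = self.genomes[keep]
        self.alive = np.ones(len(self.genomes), dtype=bool)
        self._alive_idx = None

    # -- checkpointing -------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        """Flat checkpoint: one row per living trout, genome as 40 binary columns."""
        idx = self.alive_indices
        data = {name: getattr(self, name)[idx] for name in _SCALAR_FIELDS}
        flat = self.genomes[idx].reshape(len(idx), 2 * N_LOCI)
        for locus in range(N_LOCI):
            for copy in range(2):
                data[f"g{locus:02d}_{copy}"] = flat[:, 2 * locus + copy]
        return pd.DataFrame(data)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Population":
        fields = {name: df[name].to_numpy() for name in _SCALAR_FIELDS}
        cols = [f"g{locus:02d}_{copy}" for locus in range(N_LOCI) for copy in range(2)]
        genomes = df[cols].to_numpy(dtype=np.uint8).reshape(len(df), N_LOCI, 2)
        return cls(fields, genomes)


# -- spatial queries ----------------------------------------------------


def neighbors_within_radius(
    pop: Population,
    focal: int,
    radius: float,
    predicate: np.ndarray | None = None,
) -> np.ndarray:
    """Indices of living freshwater trout within Euclidean ``radius`` of ``focal``.

    ``predicate`` is an optional boolean mask over the whole population;
    the focal fish itself is always excluded.
    """
    if radius <= 0:
        raise ValueError(f"search radius must be > 0, got {radius}")
    idx = pop.alive_indices
    mask = pop.habitat[idx] == FRESHWATER
    if predicate is not None:
        mask &= np.asarray(predicate, dtype=bool)[idx]
    cand = idx[mask]
    cand = cand[cand != focal]
    dx = pop.x[cand].astype(np.float64) - float(pop.x[focal])
    dy = pop.y[cand].astype(np.float64) - float(pop.y[focal])
    return cand[dx * dx + dy * dy <= radius * radius]


def anadromous_resident_male_ratio(
    pop: Population,
    focal: int,
    radius: float,
    resident_maturity_weeks: int = 104,
    anadromous_maturity_weeks: int = 156,
) -> float:
    """Local ratio of mature anadromous to mature resident males.

    The focal fish counts itself in the resident denominator (it is a
    resident male present at the site), which also keeps the denominator
    positive; if the denominator is nevertheless zero the ratio is
    ``inf`` so that any finite sneaking threshold is exceeded.
    """
    if radius <= 0:
        raise ValueError(f"search radius must be > 0, got {radius}")
    idx = pop.alive_indices
    males = (pop.sex[idx] == 0) & (pop.habitat[idx] == FRESHWATER)
    cand = idx[males]
    dx = pop.x[cand].astype(np.float64) - float(pop.x[focal])
    dy = pop.y[cand].astype(np.float64) - float(pop.y[focal])
    near = cand[dx * dx + dy * dy <= radius * radius]  # includes focal (distance 0)
    tact = pop.tactic[near]
    age = pop.age_weeks[near]
    n_anad = int(((tact == ANADROMOUS) & (age >= anadromous_maturity_weeks)).sum())
    n_res = int(((tact == RESIDENT) & (age >= resident_maturity_weeks)).sum())
    if n_res == 0:
        return float("inf")
    return n_anad / n_res
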