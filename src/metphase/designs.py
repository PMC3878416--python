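"""Two-phase experimental design generators.

Field phase: cultivars are laid out on a pot grid in a row-column design
with resolvable replicate blocks, each block a contiguous band of columns.

Laboratory phase: milled samples from each field block are re-randomised
onto 96-well plates.  Every sample occupies one *plate plot* — four
vertically consecutive wells in a single plate column — so a plate holds
20 test samples in columns 1–10 plus four standard samples in columns
11–12.  A small fraction of cultivars is duplicated across plates
(partial replication) so plate-to-plate variation is estimable; the two
copies of a duplicated cultivar always land on different plates, and each
plate carries one or two duplicate samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

EMPTY = "EMPTY"

PLATE_ROWS = ("A", "B", "C", "D", "E", "F", "G", "H")
N_PLATE_COLUMNS = 12
TEST_COLUMNS = tuple(range(1, 11))
STANDARD_COLUMNS = (11, 12)
SAMPLES_PER_PLATE = 20  # test samples; standards sit on top of this
#: Standard samples, identical on every plate: plot -> id.
STANDARD_IDS = ("STD1", "STD2", "STD3", "STD4")

FIELD_COLUMNS_SCHEMA = ["trial", "block", "field_row", "field_column", "cultivar"]
LAB_COLUMNS_SCHEMA = [
    "trial",
    "block",
    "day",
    "plate",
    "plate_plot",
    "plate_row",
    "plate_column",
    "cultivar",
    "copy",
    "is_standard",
]


class DesignError(ValueError):
    """Raised when a requested design is invalid or infeasible."""


def plate_plot(column: int, half: int) -> int:
    """Plot index (1..24) for a plate column and half (0=rows A–D, 1=E–H)."""
    return 2 * (column - 1) + half + 1


def plot_wells(plot: int) -> list[tuple[str, int]]:
    """The four (plate_row, plate_column) wells of a plate plot."""
    column, half = divmod(plot - 1, 2)
    rows = PLATE_ROWS[:4] if half == 0 else PLATE_ROWS[4:]
    return [(r, column + 1) for r in rows]


TEST_PLOTS = tuple(plate_plot(c, h) for c in TEST_COLUMNS for h in (0, 1))
STANDARD_PLOTS = tuple(plate_plot(c, h) for c in STANDARD_COLUMNS for h in (0, 1))


@dataclass(frozen=True)
class FieldDesign:
    """Cultivar-to-pot assignment for one trial."""

    trial: str
    n_rows: int
    n_blocks: int
    block_width: int
    table: pd.DataFrame = field(repr=False)  # FIELD_COLUMNS_SCHEMA rows

    @property
    def n_columns(self) -> int:
        return self.n_blocks * self.block_width

    def cultivars(self) -> list[str]:
        vals = self.table.loc[self.table["cultivar"] != EMPTY, "cultivar"]
        return sorted(vals.unique())

    def block_cultivars(self, block: int) -> list[str]:
        sub = self.table[(self.table["block"] == block) & (self.table["cultivar"] != EMPTY)]
        return sorted(sub["cultivar"])


@dataclass(frozen=True)
class LabDesign:
    """Well-level laboratory design for one trial (4 rows per sample)."""

    trial: str
    plates_per_day: int
    duplicates: dict[int, list[str]] = field(repr=False)  # block -> dup cultivar ids
    table: pd.DataFrame = field(repr=False)  # LAB_COLUMNS_SCHEMA rows

    @property
    def n_plates(self) -> int:
        return self.table["plate"].nunique()

    @property
    def n_samples(self) -> int:
        """Number of test samples (not wells, not standards)."""
        sub = self.table[~self.table["is_standard"]]
        return len(sub) // 4

    def block_samples(self, block: int) -> pd.DataFrame:
        """One row per test sample of a block: cultivar, copy, plate."""
        sub = self.table[(self.table["block"] == block) & (~self.table["is_standard"])]
        return (
            sub.drop_duplicates(subset=["plate", "plate_plot"])
            .loc[:, ["cultivar", "copy", "plate", "plate_plot", "day"]]
            .reset_index(drop=True)
        )


def _check_unique(cultivars: Sequence[str]) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for c in cultivars:
        if c in seen:
            dups.append(c)
        seen.add(c)
    if dups:
        raise DesignError(f"duplicate cultivar ids: {sorted(set(dups))}")


def generate_field_design(
    cultivars: Sequence[str],
    n_blocks: int = 5,
    n_rows: int = 8,
    seed: int = 0,
    trial: str = "trial1",
) -> FieldDesign:
    """Randomised row-column field layout with resolvable replicate blocks.

    Every cultivar appears exactly once per block.  Block ``b`` occupies
    the contiguous columns ``(b-1)*w+1 .. b*w`` where
    ``w = ceil(n_cultivars / n_rows)``; surplus pots (when ``n_rows * w``
    exceeds the cultivar count) are left EMPTY at the end of the block.
    Randomisation is independent between blocks and reproducible from
    ``seed``.
    """
    if n_blocks < 1 or n_rows < 1:
        raise DesignError("n_blocks and n_rows must be >= 1")
    cultivars = list(cultivars)
    if not cultivars:
        raise DesignError("empty cultivar list")
    _check_unique(cultivars)
    n = len(cultivars)
    width = math.ceil(n / n_rows)
    block_seeds = np.random.SeedSequence(seed).spawn(n_blocks)
    records: list[tuple] = []
    for b in range(1, n_blocks + 1):
        rng = np.random.default_rng(block_seeds[b - 1])
        order = list(rng.permutation(cultivars))
        order += [EMPTY] * (n_rows * width - n)
        col0 = (b - 1) * width
        i = 0
        for col in range(col0 + 1, col0 + width + 1):
            for row in range(1, n_rows + 1):
                records.append((trial, b, row, col, order[i]))
                i += 1
    table = pd.DataFrame(records, columns=FIELD_COLUMNS_SCHEMA)
    return FieldDesign(trial=trial, n_rows=n_rows, n_blocks=n_blocks, block_width=width, table=table)


def feasible_dup_range(n_plates: int) -> tuple[int, int]:
    """Duplicate-cultivar counts compatible with 1–2 duplicates per plate."""
    return math.ceil(n_plates / 2), n_plates


def _assign_duplicate_plates(
    dups: list[str], quotas: np.ndarray, rng: np.random.Generator
) -> dict[str, tuple[int, int]]:
    """Assign each duplicated cultivar's two copies to two distinct plates.

    ``quotas[p]`` is the number of duplicate samples plate ``p`` (0-based)
    must carry.  Random assignment with pairwise swap repair.
    """
    slots = np.repeat(np.arange(len(quotas)), quotas)
    assert len(slots) == 2 * len(dups)
    for _attempt in range(200):
        perm = rng.permutation(slots)
        ok = True
        for i in range(len(dups)):
            a, b = perm[2 * i], perm[2 * i + 1]
            if a != b:
                continue
            # swap the second copy with some slot of a different cultivar
            fixed = False
            for j in rng.permutation(len(perm)):
                if j // 2 == i or perm[j] == a:
                    continue
                other = j // 2
                oa, ob = perm[2 * other], perm[2 * other + 1]
                # the swap must not collapse the other cultivar's pair
                if (oa if j % 2 else ob) == a:
                    continue
                perm[2 * i + 1], perm[j] = perm[j], a
                fixed = True
                break
            if not fixed:
                ok = False
                break
        if ok:
            return {c: (int(perm[2 * i]), int(perm[2 * i + 1])) for i, c in enumerate(dups)}
    raise DesignError("could not separate duplicate copies across plates")


def generate_lab_design(
    available_samples: Mapping[int, Sequence[str]] | Sequence[Sequence[str]],
    dup_count: int | Mapping[int, int] = 0,
    plates_per_day: int = 4,
    seed: int = 0,
    trial: str = "trial1",
) -> LabDesign:
    """Partially replicated plate design re-randomising field samples.

    ``available_samples`` maps each replicate block (1-based) to the
    cultivars with a sample available from the field (a plain sequence of
    sequences is treated as blocks 1..k).  ``dup_count`` cultivars per
    block are drawn at random and processed twice, on different plates,
    with one or two duplicate samples per plate.  Plates are numbered
    consecutively across blocks in processing order and grouped into days
    of ``plates_per_day`` (the trial's last day may be short).
    """
    if not isinstance(available_samples, Mapping):
        available_samples = {b + 1: list(v) for b, v in enumerate(available_samples)}
    if plates_per_day < 1:
        raise DesignError("plates_per_day must be >= 1")
    blocks = sorted(available_samples)
    if isinstance(dup_count, Mapping):
        dup_counts = {b: int(dup_count.get(b, 0)) for b in blocks}
    else:
        dup_counts = {b: int(dup_count) for b in blocks}
    block_seeds = np.random.SeedSequence(seed).spawn(len(blocks))

    records: list[tuple] = []
    duplicates: dict[int, list[str]] = {}
    plate_offset = 0
    for bi, b in enumerate(blocks):
        avail = list(available_samples[b])
        _check_unique(avail)
        d = dup_counts[b]
        if d > len(avail):
            raise DesignError(f"block {b}: dup_count {d} exceeds available {len(avail)}")
        total = len(avail) + d
        n_plates = math.ceil(total / SAMPLES_PER_PLATE)
        if d > 0:
            lo, hi = feasible_dup_range(n_plates)
            if not lo <= d <= hi:
                raise DesignError(
                    f"block {b}: dup_count {d} infeasible for the 1-2 duplicates-per-plate "
                    f"rule on {n_plates} plates; feasible range is [{lo}, {hi}]"
                )
        rng = np.random.default_rng(block_seeds[bi])
        dups = sorted(rng.choice(avail, size=d, replace=False)) if d else []
        duplicates[b] = list(dups)

        capacities = np.full(n_plates, SAMPLES_PER_PLATE)
        capacities[-1] = total - SAMPLES_PER_PLATE * (n_plates - 1)
        # duplicate quotas: one per plate, the surplus spread at random
        if d > 0:
            quotas = np.ones(n_plates, dtype=int)
            extra = 2 * d - n_plates
            if extra > 0:
                room = np.flatnonzero(capacities >= 2)
                quotas[rng.choice(room, size=extra, replace=False)] += 1
            dup_plates = _assign_duplicate_plates(list(dups), quotas, rng)
        else:
            quotas = np.zeros(n_plates, dtype=int)
            dup_plates = {}

        # pools of (cultivar, copy) per plate
        plate_pool: list[list[tuple[str, int]]] = [[] for _ in range(n_plates)]
        for c, (p1, p2) in dup_plates.items():
            plate_pool[p1].append((c, 1))
            plate_pool[p2].append((c, 2))
        singles = [c for c in avail if c not in dup_plates]
        slots = np.repeat(np.arange(n_plates), capacities - quotas)
        slots = rng.permutation(slots)
        assert len(slots) == len(singles)
        for c, p in zip(singles, slots):
            plate_pool[p].append((c, 1))

        for p in range(n_plates):
            plate_no = plate_offset + p + 1
            pool = plate_pool[p]
            plots = rng.permutation(TEST_PLOTS)[: len(pool)]
            for (c, copy), plot in zip(pool, plots):
                for prow, pcol in plot_wells(int(plot)):
                    records.append((trial, b, 0, plate_no, int(plot), prow, pcol, c, copy, False))
            for plot, std in zip(STANDARD_PLOTS, STANDARD_IDS):
                for prow, pcol in plot_wells(plot):
                    records.append((trial, b, 0, plate_no, plot, prow, pcol, std, 1, True))
        plate_offset += n_plates

    table = pd.DataFrame(records, columns=LAB_COLUMNS_SCHEMA)
    # processing days: consecutive plates across the whole trial
    table["day"] = (table["plate"] - 1) // plates_per_day + 1
    return LabDesign(trial=trial, plates_per_day=plates_per_day, duplicates=duplicates, table=table)


def check_confounding(
    field_design: FieldDesign,
    lab_design: LabDesign,
    corr_threshold: float = 0.3,
    max_shared_threshold: int = 4,
    allow_missing: bool = False,
) -> pd.DataFrame:
    """Diagnose field-position vs laboratory-order confounding per block.

    Returns one row per block with the Spearman rank correlation between
    a sample's field column and its plate processing order, and the
    largest number of samples from any single field column that share a
    plate.  Rows exceeding either threshold are flagged.

    With ``allow_missing`` the field block may contain cultivars without
    a laboratory sample (availability mask); laboratory cultivars absent
    from the field are always an error.
    """
    rows = []
    for b in sorted(lab_design.duplicates):
        samples = lab_design.block_samples(b)
        fsub = field_design.table[
            (field_design.table["block"] == b) & (field_design.table["cultivar"] != EMPTY)
        ]
        fcol = dict(zip(fsub["cultivar"], fsub["field_column"]))
        lab_set = set(samples["cultivar"])
        field_set = set(fcol)
        extra = sorted(lab_set - field_set)
        missing = sorted(field_set - lab_set)
        if extra or (missing and not allow_missing):
            raise DesignError(
                f"block {b}: sample sets differ between field and lab; "
                f"lab-only={extra}, field-only={missing}"
            )
        cols = samples["cultivar"].map(fcol).to_numpy(float)
        order = samples["plate"].to_numpy(float)
        if len(samples) > 1 and np.ptp(cols) > 0 and np.ptp(order) > 0:
            rho = float(spearmanr(cols, order).statistic)
        else:
            rho = 0.0
        shared = (
            samples.assign(field_column=cols)
            .groupby(["plate", "field_column"])
            .size()
            .max()
        )
        rows.append(
            {
                "block": b,
                "spearman_r": rho,
                "max_column_per_plate": int(shared),
                "flagged": abs(rho) > corr_threshold or int(shared) > max_shared_threshold,
            }
        )
    return pd.DataFrame(rows)
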