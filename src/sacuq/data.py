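"""Domain types and on-disk format for saccade registers.

A *saccade* is one fixed-length eye-movement signal: 192 real samples with
amplitude normalized to [-0.5, 0.5].  A *register* is the full set of saccades
recorded from one patient examination and carries a single diagnostic label:
control (C), presymptomatic (P) or sick (S).

On disk a register is a UTF-8 text file with extension ``.reg.csv``::

    # register_id=<id> label=<C|P|S>
    <192 comma-separated decimals>
    ...

A dataset directory is a flat folder of such files, loaded in lexicographic
filename order so that downstream seeded procedures are reproducible.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

SACCADE_LENGTH = 192
AMPLITUDE_BOUND = 0.5

__all__ = [
    "SACCADE_LENGTH",
    "AMPLITUDE_BOUND",
    "ClassLabel",
    "Register",
    "DataSet",
    "SplitSpec",
    "FormatError",
    "validate_saccade",
    "read_register_file",
    "write_register_file",
    "load_dataset",
    "split_registers",
    "write_manifest",
    "dataset_structure_report",
]


class FormatError(ValueError):
    """Raised when a register file violates the canonical format."""


class ClassLabel(enum.IntEnum):
    """Diagnostic class with fixed integer encoding C=0, P=1, S=2.

    All probability vectors in the package use this class order.
    """

    C = 0
    P = 1
    S = 2

    @classmethod
    def from_string(cls, s: str) -> "ClassLabel":
        try:
            return cls[s.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown class label {s!r}; expected C, P or S") from None


N_CLASSES = len(ClassLabel)


def validate_saccade(samples, *, permissive: bool = False) -> np.ndarray:
    """Validate (and optionally rescale) one saccade signal.

    Parameters
    ----------
    samples
        Real vector; must have exactly 192 entries.
    permissive
        If True, a signal outside [-0.5, 0.5] is linearly rescaled so that
        ``max |sample| = 0.5``; off by default because silent renormalization
        can mask corrupt input.

    Returns
    -------
    float64 array of shape (192,) within [-0.5, 0.5].
    """
    arr = np.asarray(samples, dtype=np.float64)
    if arr.ndim != 1 or arr.shape[0] != SACCADE_LENGTH:
        raise ValueError(
            f"saccade must have exactly {SACCADE_LENGTH} samples, got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError("saccade contains non-finite samples")
    peak = float(np.max(np.abs(arr)))
    if peak > AMPLITUDE_BOUND:
        if not permissive:
            raise ValueError(
                f"sample amplitude {peak:.6g} outside [-{AMPLITUDE_BOUND}, {AMPLITUDE_BOUND}]"
            )
        arr = arr * (AMPLITUDE_BOUND / peak)
    return arr


@dataclass
class Register:
    """One patient's labeled collection of saccades.

    ``saccades`` is a float64 array of shape (n_saccades, 192); order is
    meaningful only for reproducibility, not for the method.
    """

    register_id: str
    label: ClassLabel
    saccades: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.saccades, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[1] != SACCADE_LENGTH:
            raise ValueError(
                f"register saccades must have shape (n, {SACCADE_LENGTH}), got {arr.shape}"
            )
        if arr.shape[0] < 1:
            raise ValueError("register must contain at least one saccade")
        self.saccades = arr
        self.label = ClassLabel(self.label)

    @property
    def n_saccades(self) -> int:
        return int(self.saccades.shape[0])


@dataclass
class DataSet:
    """A sequence of registers with unique ids."""

    registers: list[Register] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.register_id for r in self.registers]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate register ids: {dupes}")

    def __len__(self) -> int:
        return len(self.registers)

    def __iter__(self):
        return iter(self.registers)

    @property
    def n_saccades(self) -> int:
        return sum(r.n_saccades for r in self.registers)

    def labels(self) -> list[ClassLabel]:
        return [r.label for r in self.registers]

    def saccade_matrix(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Stack all saccades; returns (signals, inherited labels, register ids).

        Each saccade inherits the label of its parent register — for
        presymptomatic registers this deliberately injects label noise at the
        saccade level, which is what the uncertainty pipeline exploits.
        """
        if not self.registers:
            return (
                np.empty((0, SACCADE_LENGTH)),
                np.empty((0,), dtype=np.int64),
                [],
            )
        x = np.concatenate([r.saccades for r in self.registers], axis=0)
        y = np.concatenate(
            [np.full(r.n_saccades, int(r.label), dtype=np.int64) for r in self.registers]
        )
        ids = [r.register_id for r in self.registers for _ in range(r.n_saccades)]
        return x, y, ids


@dataclass(frozen=True)
class SplitSpec:
    """Register-level split fractions (train, validation, test) and seed."""

    fractions: tuple[float, float, float] = (0.4, 0.4, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.fractions) != 3 or any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be three non-negative reals")
        if not math.isclose(sum(self.fractions), 1.0, abs_tol=1e-9):
            raise ValueError(f"fractions must sum to 1, got {sum(self.fractions)}")


def read_register_file(path, *, permissive: bool = False) -> Register:
    """Parse one canonical ``.reg.csv`` register file."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise FormatError(f"{path}: line 1 is not a header comment: {header!r}")
        fields = dict(
            tok.split("=", 1) for tok in header.lstrip("#").split() if "=" in tok
        )
        if "register_id" not in fields or "label" not in fields:
            raise FormatError(
                f"{path}: header must contain register_id=<id> label=<C|P|S>: {header!r}"
            )
        label = ClassLabel.from_string(fields["label"])
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            values = line.split(",")
            if len(values) != SACCADE_LENGTH:
                raise FormatError(
                    f"{path}: line {lineno} has {len(values)} values, "
                    f"expected {SACCADE_LENGTH}"
                )
            try:
                row = np.array([float(v) for v in values], dtype=np.float64)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            rows.append(validate_saccade(row, permissive=permissive))
    if not rows:
        raise FormatError(f"{path}: register file contains no saccade rows")
    return Register(fields["register_id"], label, np.vstack(rows))


def write_register_file(register: Register, path) -> Path:
    """Write one register in the canonical format (17 significant digits)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# register_id={register.register_id} label={register.label.name}\n")
        for row in register.saccades:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")
    return path


def load_dataset(directory, *, permissive: bool = False) -> DataSet:
    """Load every ``.reg.csv`` file from a flat directory, lexicographically."""
    directory = Path(directory)
    files = sorted(directory.glob("*.reg.csv"))
    if not files:
        raise FileNotFoundError(f"no .reg.csv files in {directory}")
    return DataSet([read_register_file(f, permissive=permissive) for f in files])


def _allocate(n: int, fractions: Sequence[float]) -> list[int]:
    # floor allocation, remainders to train (index 0) first, then validation
    counts = [int(math.floor(n * f)) for f in fractions]
    remainder = n - sum(counts)
    for i in range(remainder):
        counts[i % 3] += 1
    return counts


def split_registers(
    dataset: DataSet, spec: SplitSpec
) -> tuple[DataSet, DataSet, DataSet]:
    """Stratified register-level train/validation/test split.

    Within each class, register order is shuffled by the spec seed and the
    class's registers are allocated by floor counts with remainders going to
    train first (maximizing training data).  Identical seed gives identical
    membership.
    """
    if len(dataset) == 0:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(spec.seed)
    parts: tuple[list[Register], list[Register], list[Register]] = ([], [], [])
    for label in ClassLabel:
        members = [r for r in dataset if r.label == label]
        if not members:
            continue
        order = rng.permutation(len(members))
        counts = _allocate(len(members), spec.fractions)
        start = 0
        for part, count in zip(parts, counts):
            part.extend(members[i] for i in order[start : start + count])
            start += count
    return tuple(DataSet(p) for p in parts)  # type: ignore[return-value]


def write_manifest(
    directory,
    splits: dict[str, DataSet] | None = None,
    dataset: DataSet | None = None,
) -> Path:
    """Emit a TSV manifest (register_id, label, n_saccades, split)."""
    directory = Path(directory)
    assignment: dict[str, str] = {}
    registers: list[Register] = []
    if splits is not None:
        for name, part in splits.items():
            for r in part:
                assignment[r.register_id] = name
                registers.append(r)
    elif dataset is not None:
        registers = list(dataset)
    else:
        raise ValueError("provide either splits or dataset")
    path = directory / "manifest.tsv"
    with path.open("w", encoding="utf-8") as fh:
        fh.write("register_id\tlabel\tn_saccades\tsplit\n")
        for r in sorted(registers, key=lambda r: r.register_id):
            fh.write(
                f"{r.register_id}\t{r.label.name}\t{r.n_saccades}\t"
                f"{assignment.get(r.register_id, '-')}\n"
            )
    return path


def dataset_structure_report(directory) -> dict:
    """Structural summary of a dataset directory.

    Reports register count, total saccade count, the set of saccade lengths
    encountered and the maximum absolute amplitude — the quantities one checks
    against a deposit's published description before analysis.
    """
    ds = load_dataset(directory)
    max_abs = max(float(np.max(np.abs(r.saccades))) for r in ds)
    per_class = {
        label.name: sum(1 for r in ds if r.label == label) for label in ClassLabel
    }
    return {
        "n_registers": len(ds),
        "n_saccades": ds.n_saccades,
        "saccade_lengths": sorted({r.saccades.shape[1] for r in ds}),
        "max_abs_amplitude": max_abs,
        "registers_per_class": per_class,
    }
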