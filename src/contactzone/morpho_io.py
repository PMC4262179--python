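"""Reading and writing landmark data in the TPS dialect.

TPS files are the de-facto interchange format of landmark digitisation
software: records start with an ``LM=k`` header followed by ``k``
whitespace-separated ``x y`` coordinate lines, with optional ``IMAGE=``,
``ID=`` and ``SCALE=`` lines.  Group labels (parental lineage, hybrid cross
class) are not part of the format and are supplied through a two-column
sidecar file mapping specimen id to group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

VALID_GROUP_PREFIXES = ("parentA", "parentB", "F1", "backcrossA", "backcrossB", "F2", "wild:")


class TPSParseError(ValueError):
    """Raised when a TPS record is malformed."""


@dataclass
class LandmarkConfiguration:
    """A single specimen's 2-D landmark set.

    Coordinates are stored with any ``SCALE=`` factor already applied, in a
    ``(k, 2)`` float array.  ``group`` is the experiment label (parental
    lineage, hybrid cross class, or ``wild:<site>``).
    """

    specimen_id: str
    coords: np.ndarray
    group: str | None = None
    scale: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(f"coords must be (k, 2), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates in specimen {self.specimen_id!r}")

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]


@dataclass
class LandmarkDataset:
    """A collection of landmark configurations sharing a common scheme."""

    configurations: list[LandmarkConfiguration] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.configurations:
            raise ValueError("dataset must contain at least one configuration")
        ks = {c.n_landmarks for c in self.configurations}
        if len(ks) > 1:
            raise ValueError(f"inconsistent landmark counts across dataset: {sorted(ks)}")
        ids = [c.specimen_id for c in self.configurations]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate specimen ids: {dupes}")

    @property
    def landmark_count(self) -> int:
        return self.configurations[0].n_landmarks

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self):
        return iter(self.configurations)

    def coords_array(self) -> np.ndarray:
        """All coordinates stacked as an (n_specimens, k, 2) array."""
        return np.stack([c.coords for c in self.configurations])

    def groups(self) -> list[str | None]:
        return [c.group for c in self.configurations]

    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    def with_groups(self, mapping: Mapping[str, str], strict: bool = True) -> "LandmarkDataset":
        """Return a copy with group labels attached from a sidecar mapping."""
        missing = [c.specimen_id for c in self.configurations if c.specimen_id not in mapping]
        if missing and strict:
            raise KeyError(f"specimens missing from group map: {missing[:10]}")
        return LandmarkDataset(
            [
                LandmarkConfiguration(
                    c.specimen_id, c.coords.copy(), mapping.get(c.specimen_id, c.group), c.scale
                )
                for c in self.configurations
            ]
        )


def _parse_key(line: str) -> tuple[str, str] | None:
    if "=" not in line:
        return None
    key, _, value = line.partition("=")
    return key.strip().upper(), value.strip()


def read_tps(path: str | Path) -> LandmarkDataset:
    """Parse a TPS file into a :class:`LandmarkDataset`.

    Accepts ``LM=`` headers in any case; applies ``SCALE=`` multiplicatively
    to coordinates; uses ``ID=`` as the specimen id, falling back to the
    0-based record index.

    Raises
    ------
    TPSParseError
        If the declared landmark count of a record disagrees with its
        coordinate lines, or a coordinate line cannot be parsed.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    records: list[dict] = []
    current: dict | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        kv = _parse_key(line)
        if kv is not None and kv[0] == "LM":
            if current is not None:
                records.append(current)
            try:
                k = int(kv[1])
            except ValueError as exc:
                raise TPSParseError(f"line {lineno}: invalid LM= value {kv[1]!r}") from exc
            current = {"k": k, "coords": [], "id": None, "scale": None, "line": lineno}
            continue
        if current is None:
            raise TPSParseError(f"line {lineno}: content before first LM= header")
        if kv is not None and kv[0] in ("ID", "IMAGE", "SCALE"):
            if kv[0] == "ID":
                current["id"] = kv[1]
            elif kv[0] == "SCALE":
                current["scale"] = float(kv[1])
            continue
        parts = line.split()
        if len(parts) != 2:
            raise TPSParseError(f"line {lineno}: expected 'x y' coordinate line, got {line!r}")
        try:
            current["coords"].append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise TPSParseError(f"line {lineno}: non-numeric coordinate {line!r}") from exc
    if current is not None:
        records.append(current)
    if not records:
        raise TPSParseError(f"{path}: no TPS records found")

    configs = []
    for idx, rec in enumerate(records):
        if len(rec["coords"]) != rec["k"]:
            raise TPSParseError(
                f"record {idx + 1} (line {rec['line']}): LM={rec['k']} but "
                f"{len(rec['coords'])} coordinate lines"
            )
        coords = np.array(rec["coords"], dtype=float)
        if rec["scale"] is not None:
            coords = coords * rec["scale"]
        configs.append(
            LandmarkConfiguration(
                specimen_id=rec["id"] if rec["id"] is not None else str(idx),
                coords=coords,
                scale=rec["scale"],
            )
        )
    return LandmarkDataset(configs)


def write_tps(dataset: LandmarkDataset, path: str | Path) -> Path:
    """Write a dataset in TPS format; round-trips through :func:`read_tps`.

    Coordinates are written at full repr precision so that a read-back
    reproduces them exactly.  Stored coordinates already include any scale,
    so no SCALE= line is emitted.
    """
    path = Path(path)
    out = []
    for cfg in dataset:
        out.append(f"LM={cfg.n_landmarks}")
        for x, y in cfg.coords:
            out.append(f"{float(x)!r} {float(y)!r}")
        out.append(f"ID={cfg.specimen_id}")
    path.write_text("\n".join(out) + "\n")
    return path


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (specimen_id, group) delimited sidecar file.

    Columns may be separated by tabs, commas or whitespace.  Lines starting
    with ``#`` are ignored.
    """
    mapping: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        for sep in ("\t", ","):
            if sep in line:
                parts = [p.strip() for p in line.split(sep)]
                break
        else:
            parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path} line {lineno}: expected two columns, got {line!r}")
        sid, group = parts
        if sid in mapping:
            raise ValueError(f"{path} line {lineno}: duplicate specimen id {sid!r}")
        mapping[sid] = group
    return mapping


def write_group_map(mapping: Mapping[str, str] | Iterable[tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    items = mapping.items() if isinstance(mapping, Mapping) else mapping
    path.write_text("\n".join(f"{sid}\t{grp}" for sid, grp in items) + "\n")
    return path
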