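"""Landmark, template, and metadata I/O.

Reads the fibular landmark template (fixed landmarks, curve and surface
semilandmarks, assigned to the proximal or distal epiphysis), specimen
coordinate files in classic TPS landmark format or delimited tables, and
specimen metadata; assembles them into analysis-ready samples and splits a
sample into per-epiphysis datasets.

All coordinates are millimetres, ordered (x, y, z), left-side bones by
contract. Point labels are opaque strings: the anatomical template skips
some numeric labels, so nothing here assumes label contiguity.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

ROLES = ("fixed", "curve-semilandmark", "surface-semilandmark")
REGIONS = ("proximal", "distal")

_CURVE_ID_RE = re.compile(r"^C_(\w+)->(\w+)$")


class TemplateError(ValueError):
    """Malformed or internally inconsistent template file."""


class LandmarkFileError(ValueError):
    """Malformed coordinate file or specimen/template size mismatch."""


class MetadataError(ValueError):
    """Malformed or inconsistent specimen metadata."""


@dataclass(frozen=True)
class TemplatePoint:
    label: str
    role: str
    region: str
    anatomical_name: str = ""
    patch: str | None = None


@dataclass
class TemplateDefinition:
    """Ordered landmark template: point roles, curve orderings, surface patches.

    ``curves`` maps a curve id to its ordered label sequence including the
    fixed endpoint labels; ``surface_patches`` maps a patch name to its
    member labels in template order.
    """

    points: list[TemplatePoint]
    curves: dict[str, list[str]] = field(default_factory=dict)
    surface_patches: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {p.label: i for i, p in enumerate(self.points)}
        if len(self._index) != len(self.points):
            seen: set[str] = set()
            dup = next(p.label for p in self.points if p.label in seen or seen.add(p.label))
            raise TemplateError(f"duplicate point label {dup!r}")

    @property
    def size(self) -> int:
        return len(self.points)

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.points]

    def index_of(self, label: str) -> int:
        return self._index[label]

    def role_counts(self) -> dict[str, int]:
        counts = {role: 0 for role in ROLES}
        for p in self.points:
            counts[p.role] += 1
        return counts

    def region_counts(self) -> dict[str, int]:
        counts = {region: 0 for region in REGIONS}
        for p in self.points:
            counts[p.region] += 1
        return counts

    def points_in_region(self, region: str) -> list[TemplatePoint]:
        return [p for p in self.points if p.region == region]

    def validate(self) -> None:
        for p in self.points:
            if p.role not in ROLES:
                raise TemplateError(f"point {p.label!r}: unknown role {p.role!r}")
            if p.region not in REGIONS:
                raise TemplateError(f"point {p.label!r}: unknown region {p.region!r}")
        for cid, seq in self.curves.items():
            if len(seq) < 2:
                raise TemplateError(f"curve {cid!r} has fewer than 2 points")
            for label in seq:
                if label not in self._index:
                    raise TemplateError(f"curve {cid!r} references unknown label {label!r}")
        for name, members in self.surface_patches.items():
            for label in members:
                if label not in self._index:
                    raise TemplateError(f"patch {name!r} references unknown label {label!r}")
        in_curve = {lab for seq in self.curves.values() for lab in seq}
        for p in self.points:
            if p.role == "curve-semilandmark" and p.label not in in_curve:
                raise TemplateError(f"curve semilandmark {p.label!r} belongs to no curve")
            if p.role == "surface-semilandmark" and p.patch is None:
                raise TemplateError(f"surface semilandmark {p.label!r} has no patch")

    def restrict_to_region(self, region: str) -> "TemplateDefinition":
        """Region-restricted sub-template preserving point order."""
        pts = self.points_in_region(region)
        if not pts:
            raise TemplateError(f"template has no {region!r} points")
        keep = {p.label for p in pts}
        curves = {
            cid: seq for cid, seq in self.curves.items() if all(l in keep for l in seq)
        }
        patches = {
            name: [l for l in members if l in keep]
            for name, members in self.surface_patches.items()
        }
        patches = {name: m for name, m in patches.items() if m}
        return TemplateDefinition(points=pts, curves=curves, surface_patches=patches)


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 3D landmark coordinates (mm)."""

    specimen_id: str
    coords: np.ndarray
    template_ref: TemplateDefinition | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise LandmarkFileError(
                f"specimen {self.specimen_id!r}: coordinates must be K x 3"
            )
        if not np.all(np.isfinite(self.coords)):
            raise LandmarkFileError(
                f"specimen {self.specimen_id!r}: non-finite coordinate"
            )
        if self.template_ref is not None and self.coords.shape[0] != self.template_ref.size:
            raise LandmarkFileError(
                f"specimen {self.specimen_id!r}: {self.coords.shape[0]} points, "
                f"template has {self.template_ref.size}"
            )


@dataclass(frozen=True)
class SpecimenMetadata:
    specimen_id: str
    sex: str
    population: str
    age_years: int | None = None
    side: str = "left"

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise MetadataError(
                f"specimen {self.specimen_id!r}: sex must be M or F, got {self.sex!r}"
            )
        if self.age_years is not None and not (0 < self.age_years < 120):
            raise MetadataError(
                f"specimen {self.specimen_id!r}: implausible age {self.age_years}"
            )


@dataclass
class Sample:
    """Joined landmark configurations and metadata for one analysis."""

    configurations: list[LandmarkConfiguration]
    metadata: dict[str, SpecimenMetadata]
    template: TemplateDefinition
    region: str = "both"

    def __post_init__(self) -> None:
        ids = [c.specimen_id for c in self.configurations]
        if len(set(ids)) != len(ids):
            raise LandmarkFileError("duplicate specimen ids in sample")
        missing = [i for i in ids if i not in self.metadata]
        if missing:
            raise MetadataError(f"configurations without metadata: {missing}")

    def __len__(self) -> int:
        return len(self.configurations)

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    def coord_array(self) -> np.ndarray:
        """(N, K, 3) stacked coordinates."""
        return np.stack([c.coords for c in self.configurations])

    def labels_for(self, attribute: str) -> np.ndarray:
        """Per-specimen metadata column ('sex' or 'population'), sample order."""
        return np.array(
            [getattr(self.metadata[i], attribute) for i in self.specimen_ids]
        )

    def subset(self, specimen_ids: list[str]) -> "Sample":
        keep = set(specimen_ids)
        configs = [c for c in self.configurations if c.specimen_id in keep]
        meta = {c.specimen_id: self.metadata[c.specimen_id] for c in configs}
        return Sample(configs, meta, self.template, self.region)


# ---------------------------------------------------------------------------
# template files


def _split_multi(value: str) -> list[str]:
    return [v.strip() for v in str(value).split(";") if v.strip()]


def read_template(path: str | Path) -> TemplateDefinition:
    """Read a template table (columns: label, role, region, curve_id,
    curve_order, patch, anatomical_name).

    Curve ids of the form ``C_<i>-><j>`` implicitly anchor on fixed landmarks
    ``L<i>`` and ``L<j>``; those labels must exist in the point list.  Any row
    may also declare explicit curve membership (``curve_id``/``curve_order``,
    ';'-separated for multiple curves).
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - reported as a parse error
        raise TemplateError(f"{path}: cannot parse template table: {exc}") from exc
    required = {"label", "role", "region"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise TemplateError(f"{path}: missing columns {sorted(missing_cols)}")

    points: list[TemplatePoint] = []
    memberships: dict[str, list[tuple[float, str]]] = {}
    for row_no, row in enumerate(table.itertuples(index=False), start=2):
        label = str(row.label).strip()
        role = str(row.role).strip()
        region = str(row.region).strip()
        if not label or role not in ROLES or region not in REGIONS:
            raise TemplateError(
                f"{path}: line {row_no}: malformed row "
                f"(label={label!r}, role={role!r}, region={region!r})"
            )
        patch = getattr(row, "patch", "") or None
        points.append(
            TemplatePoint(
                label=label,
                role=role,
                region=region,
                anatomical_name=str(getattr(row, "anatomical_name", "")),
                patch=str(patch).strip() if patch else None,
            )
        )
        curve_ids = _split_multi(getattr(row, "curve_id", ""))
        orders = _split_multi(getattr(row, "curve_order", ""))
        if curve_ids:
            if len(orders) != len(curve_ids):
                raise TemplateError(
                    f"{path}: line {row_no}: curve_id/curve_order length mismatch"
                )
            for cid, order in zip(curve_ids, orders):
                try:
                    pos = float(order)
                except ValueError as exc:
                    raise TemplateError(
                        f"{path}: line {row_no}: non-numeric curve_order {order!r}"
                    ) from exc
                memberships.setdefault(cid, []).append((pos, label))

    label_set = {p.label for p in points}
    curves: dict[str, list[str]] = {}
    for cid, entries in memberships.items():
        seq = [lab for _, lab in sorted(entries, key=lambda e: e[0])]
        match = _CURVE_ID_RE.match(cid)
        if match:
            start, end = f"L{match.group(1)}", f"L{match.group(2)}"
            for endpoint in (start, end):
                if endpoint not in label_set:
                    raise TemplateError(
                        f"curve {cid!r} references unknown label {endpoint!r}"
                    )
            if not seq or seq[0] != start:
                seq.insert(0, start)
            if seq[-1] != end or len(seq) == 1:
                seq.append(end)
        curves[cid] = seq

    patches: dict[str, list[str]] = {}
    for p in points:
        if p.patch:
            patches.setdefault(p.patch, []).append(p.label)

    template = TemplateDefinition(points=points, curves=curves, surface_patches=patches)
    template.validate()
    return template


def load_fibula_template() -> TemplateDefinition:
    """The packaged 142-point left-fibula template (16 fixed landmarks,
    25 curve semilandmarks, 101 surface semilandmarks, split into proximal
    and distal epiphyses)."""
    with resources.as_file(
        resources.files("fibmorph.data") / "fibula_template.csv"
    ) as path:
        return read_template(path)


def write_template(template: TemplateDefinition, path: str | Path) -> None:
    rows = []
    for p in template.points:
        cids, orders = [], []
        for cid, seq in template.curves.items():
            if p.label in seq:
                # fixed endpoints of pattern curves are implicit on read
                if p.role == "fixed" and _CURVE_ID_RE.match(cid):
                    continue
                cids.append(cid)
                orders.append(str(seq.index(p.label)))
        rows.append(
            {
                "label": p.label,
                "role": p.role,
                "region": p.region,
                "curve_id": ";".join(cids),
                "curve_order": ";".join(orders),
                "patch": p.patch or "",
                "anatomical_name": p.anatomical_name,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# landmark coordinate files


def read_landmark_file(
    path: str | Path, template: TemplateDefinition | None = None
) -> list[LandmarkConfiguration]:
    """Read specimen coordinates from a TPS landmark file or delimited table.

    TPS files are detected by their ``LM3=`` record headers; anything else is
    parsed as a wide (``x1..zK`` columns) or long (``label,x,y,z`` per row)
    delimited table.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        head = fh.read(64)
    if head.lstrip().upper().startswith("LM"):
        configs = _read_tps(path)
    else:
        configs = _read_table(path, template)
    if template is not None:
        for c in configs:
            if c.coords.shape[0] != template.size:
                raise LandmarkFileError(
                    f"specimen {c.specimen_id!r}: {c.coords.shape[0]} points, "
                    f"template has {template.size}"
                )
            c.template_ref = template
    return configs


def _read_tps(path: Path) -> list[LandmarkConfiguration]:
    configs: list[LandmarkConfiguration] = []
    coords: list[list[float]] = []
    expected: int | None = None
    specimen_id: str | None = None
    n_anonymous = 0

    def flush(line_no: int) -> None:
        nonlocal coords, expected, specimen_id, n_anonymous
        if expected is None:
            return
        if len(coords) != expected:
            raise LandmarkFileError(
                f"{path}: specimen {specimen_id or '<unnamed>'}: "
                f"{len(coords)} points, header declared {expected} (line {line_no})"
            )
        if specimen_id is None:
            specimen_id = f"specimen_{n_anonymous}"
            n_anonymous += 1
        configs.append(LandmarkConfiguration(specimen_id, np.array(coords)))
        coords, expected, specimen_id = [], None, None

    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3=") or upper.startswith("LM="):
                flush(line_no)
                try:
                    expected = int(line.split("=", 1)[1])
                except ValueError as exc:
                    raise LandmarkFileError(
                        f"{path}: line {line_no}: bad LM3 header {line!r}"
                    ) from exc
            elif upper.startswith("ID="):
                specimen_id = line.split("=", 1)[1].strip()
            elif "=" in line and not line[0].isdigit() and not line[0] in "+-.":
                continue  # other TPS record types (SCALE=, IMAGE=, ...)
            else:
                parts = line.split()
                if len(parts) != 3:
                    raise LandmarkFileError(
                        f"{path}: line {line_no}: expected 3 coordinates, got {line!r}"
                    )
                try:
                    coords.append([float(v) for v in parts])
                except ValueError as exc:
                    raise LandmarkFileError(
                        f"{path}: line {line_no}: non-numeric coordinate in {line!r}"
                    ) from exc
    flush(line_no + 1 if "line_no" in locals() else 0)
    if not configs:
        raise LandmarkFileError(f"{path}: no specimens found")
    return configs


def _read_table(
    path: Path, template: TemplateDefinition | None
) -> list[LandmarkConfiguration]:
    table = pd.read_csv(path)
    cols = set(table.columns)
    if {"specimen_id", "label", "x", "y", "z"} <= cols:
        return _read_long_table(path, table, template)
    wide_re = re.compile(r"^([xyz])(\d+)$")
    axis_cols = sorted(
        (int(m.group(2)), m.group(1), c)
        for c in table.columns
        if (m := wide_re.match(c))
    )
    if not axis_cols or "specimen_id" not in cols:
        raise LandmarkFileError(
            f"{path}: not a recognised coordinate table "
            "(need specimen_id + label,x,y,z or x1..zK columns)"
        )
    k = max(i for i, _, _ in axis_cols)
    configs = []
    for _, row in table.iterrows():
        try:
            coords = np.array(
                [[float(row[f"{ax}{i}"]) for ax in "xyz"] for i in range(1, k + 1)]
            )
        except (ValueError, KeyError) as exc:
            raise LandmarkFileError(
                f"{path}: specimen {row['specimen_id']!r}: bad coordinates: {exc}"
            ) from exc
        configs.append(LandmarkConfiguration(str(row["specimen_id"]), coords))
    return configs


def _read_long_table(
    path: Path, table: pd.DataFrame, template: TemplateDefinition | None
) -> list[LandmarkConfiguration]:
    configs = []
    for sid, group in table.groupby("specimen_id", sort=False):
        if template is not None:
            order = {lab: i for i, lab in enumerate(template.labels)}
            unknown = [l for l in group["label"] if l not in order]
            if unknown:
                raise LandmarkFileError(
                    f"{path}: specimen {sid!r}: labels not in template: {unknown[:5]}"
                )
            group = group.sort_values("label", key=lambda s: s.map(order))
        coords = group[["x", "y", "z"]].to_numpy(dtype=float)
        configs.append(LandmarkConfiguration(str(sid), coords))
    return configs


def write_tps(configs: list[LandmarkConfiguration], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for c in configs:
            fh.write(f"LM3={c.coords.shape[0]}\n")
            for x, y, z in c.coords:
                fh.write(f"{x:.9f} {y:.9f} {z:.9f}\n")
            fh.write(f"ID={c.specimen_id}\n")


def write_wide_table(configs: list[LandmarkConfiguration], path: str | Path) -> None:
    k = configs[0].coords.shape[0]
    cols = [f"{ax}{i}" for i in range(1, k + 1) for ax in "xyz"]
    rows = [
        dict(zip(cols, c.coords.reshape(-1)), specimen_id=c.specimen_id)
        for c in configs
    ]
    pd.DataFrame(rows)[["specimen_id", *cols]].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# metadata


def read_metadata(path: str | Path) -> dict[str, SpecimenMetadata]:
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"specimen_id", "sex", "population"}
    missing = required - set(table.columns)
    if missing:
        raise MetadataError(f"{path}: missing columns {sorted(missing)}")
    dup = table["specimen_id"][table["specimen_id"].duplicated()].tolist()
    if dup:
        raise MetadataError(f"{path}: duplicate specimen ids: {sorted(set(dup))}")
    records: dict[str, SpecimenMetadata] = {}
    for _, row in table.iterrows():
        age_raw = str(row.get("age", "")).strip()
        age = int(float(age_raw)) if age_raw else None
        records[row["specimen_id"]] = SpecimenMetadata(
            specimen_id=row["specimen_id"],
            sex=row["sex"].strip(),
            population=row["population"].strip(),
            age_years=age,
            side=str(row.get("side", "left")).strip() or "left",
        )
    return records


def write_metadata(metadata: dict[str, SpecimenMetadata], path: str | Path) -> None:
    rows = [
        {
            "specimen_id": m.specimen_id,
            "sex": m.sex,
            "population": m.population,
            "age": "" if m.age_years is None else m.age_years,
            "side": m.side,
        }
        for m in metadata.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# sample assembly


def assemble_sample(
    configs: list[LandmarkConfiguration],
    metadata: dict[str, SpecimenMetadata],
    template: TemplateDefinition | None = None,
    region: str = "both",
) -> Sample:
    """Join configurations with metadata; specimens without a metadata record
    are dropped with a warning."""
    if template is None:
        templates = {id(c.template_ref): c.template_ref for c in configs}
        if len(templates) != 1 or None in templates.values():
            raise LandmarkFileError("configurations carry no common template")
        template = next(iter(templates.values()))
    kept, dropped = [], []
    for c in configs:
        (kept if c.specimen_id in metadata else dropped).append(c)
    if dropped:
        warnings.warn(
            "dropping specimens without metadata: "
            + ", ".join(c.specimen_id for c in dropped),
            stacklevel=2,
        )
    if not kept:
        raise MetadataError("no configuration has a matching metadata record")
    meta = {c.specimen_id: metadata[c.specimen_id] for c in kept}
    return Sample(kept, meta, template, region)


def split_by_region(sample: Sample) -> tuple[Sample, Sample]:
    """Split a full-template sample into proximal and distal samples.

    Point order is preserved within each region; the two outputs partition
    the template.
    """
    out = []
    for region in REGIONS:
        sub_template = sample.template.restrict_to_region(region)
        idx = [
            sample.template.index_of(p.label) for p in sub_template.points
        ]
        configs = [
            LandmarkConfiguration(c.specimen_id, c.coords[idx], sub_template)
            for c in sample.configurations
        ]
        out.append(Sample(configs, dict(sample.metadata), sub_template, region))
    return out[0], out[1]
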