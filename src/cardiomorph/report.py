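"""Per-image analysis reports: tabular export, re-import, manual correction.

The per-instance table and the per-class summary are written as CSV
(UTF-8, dot decimal separator); an XLSX mirror with both sheets is
optional.  The manual-correction loop is file-based: the analyst reads
instance ids off the overlay image, lists the ids to discard in a plain
text file (one id per line, ``#`` comments allowed), and re-summarization
recomputes every summary and relation from the surviving records without
re-segmentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .morphometry import CLASS_CAPILLARY, CLASS_CM, InstanceRecord
from .relations import (
    ContactResult,
    ExpressionResult,
    summarize_image,
)

logger = logging.getLogger(__name__)

INSTANCE_COLUMNS = [
    "instance_id",
    "class",
    "area_um2",
    "feret_max_um",
    "feret_min_um",
    "min_feret_angle_deg",
    "centroid_x_um",
    "centroid_y_um",
    "pixel_count",
    "touches_border",
    "capillary_contacts",
    "cc_per_area_um2",
    "expression_pct",
    "host_cm_id",
    "reason",
]


@dataclass
class ImageReport:
    """All results for one analyzed image."""

    image_id: str
    records: list[InstanceRecord]
    config: AnalysisConfig
    microns_per_pixel: float
    contacts: list[ContactResult] | None = None
    expressions: list[ExpressionResult] | None = None
    excluded: list[InstanceRecord] = field(default_factory=list)

    @property
    def class_summaries(self) -> pd.DataFrame:
        return summarize_image(self.records, self.contacts, self.expressions)

    def cm_records(self) -> list[InstanceRecord]:
        return [r for r in self.records if r.cls == CLASS_CM]

    def instance_table(self) -> pd.DataFrame:
        contact_by_cm = {c.cm_id: c for c in self.contacts or []}
        expr_by_cm = {e.cm_id: e for e in self.expressions or []}
        rows = []
        for r in self.records:
            c = contact_by_cm.get(r.instance_id)
            e = expr_by_cm.get(r.instance_id)
            rows.append(
                {
                    "instance_id": r.instance_id,
                    "class": r.cls,
                    "area_um2": r.area_um2,
                    "feret_max_um": r.feret_max_um,
                    "feret_min_um": r.feret_min_um,
                    "min_feret_angle_deg": r.min_feret_angle_deg,
                    "centroid_x_um": r.centroid_x_um,
                    "centroid_y_um": r.centroid_y_um,
                    "pixel_count": r.pixel_count,
                    "touches_border": r.touches_border,
                    "capillary_contacts": c.n_contacts if c else np.nan,
                    "cc_per_area_um2": c.cc_per_area if c else np.nan,
                    "expression_pct": e.positive_pct if e else np.nan,
                    "host_cm_id": r.host_cm_id if r.host_cm_id is not None else np.nan,
                    "reason": r.reason,
                }
            )
        return pd.DataFrame(rows, columns=INSTANCE_COLUMNS)


def write_report(
    report: ImageReport, path_prefix: str | Path, xlsx: bool = False
) -> dict[str, Path]:
    """Write ``<prefix>_instances.csv`` and ``<prefix>_summary.csv``.

    With ``xlsx=True`` an Excel mirror ``<prefix>.xlsx`` holds both tables
    as sheets.  Returns the written paths.  Empty reports produce
    headers-only tables.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    instances = report.instance_table()
    summary = report.class_summaries
    paths = {
        "instances": prefix.with_name(prefix.name + "_instances.csv"),
        "summary": prefix.with_name(prefix.name + "_summary.csv"),
    }
    instances.to_csv(paths["instances"], index=False)
    summary.to_csv(paths["summary"], index=False)
    if report.contacts is not None:
        contacts = pd.DataFrame(
            [
                {
                    "cm_id": c.cm_id,
                    "n_contacts": c.n_contacts,
                    "cc_per_area_um2": c.cc_per_area,
                    "capillary_ids": ";".join(str(i) for i in c.capillary_ids),
                }
                for c in report.contacts
            ],
            columns=["cm_id", "n_contacts", "cc_per_area_um2", "capillary_ids"],
        )
        paths["contacts"] = prefix.with_name(prefix.name + "_contacts.csv")
        contacts.to_csv(paths["contacts"], index=False)
    if report.expressions is not None:
        expr = pd.DataFrame(
            [
                {"cm_id": e.cm_id, "positive_pct": e.positive_pct}
                for e in report.expressions
            ],
            columns=["cm_id", "positive_pct"],
        )
        paths["expression"] = prefix.with_name(prefix.name + "_expression.csv")
        expr.to_csv(paths["expression"], index=False)
    if xlsx:
        xlsx_path = prefix.with_suffix(".xlsx")
        with pd.ExcelWriter(xlsx_path, engine="openpyxl") as xw:
            instances.to_excel(xw, sheet_name="instances", index=False)
            summary.to_excel(xw, sheet_name="summary", index=False)
        paths["xlsx"] = xlsx_path
    return paths


def read_instance_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def records_from_table(table: pd.DataFrame) -> list[InstanceRecord]:
    """Rebuild :class:`InstanceRecord` objects from a written instance table."""
    records = []
    for _, row in table.iterrows():
        records.append(
            InstanceRecord(
                instance_id=int(row["instance_id"]),
                cls=str(row["class"]),
                pixel_count=int(row["pixel_count"]),
                area_um2=float(row["area_um2"]),
                feret_max_um=float(row["feret_max_um"]),
                feret_min_um=float(row["feret_min_um"]),
                min_feret_angle_deg=float(row["min_feret_angle_deg"]),
                centroid_x_um=float(row["centroid_x_um"]),
                centroid_y_um=float(row["centroid_y_um"]),
                touches_border=bool(row["touches_border"]),
                reason="" if pd.isna(row.get("reason")) else str(row["reason"]),
                host_cm_id=None
                if pd.isna(row.get("host_cm_id"))
                else int(row["host_cm_id"]),
            )
        )
    return records


def load_report(
    path_prefix: str | Path,
    config: AnalysisConfig,
    microns_per_pixel: float,
    image_id: str | None = None,
) -> ImageReport:
    """Rebuild an :class:`ImageReport` from previously written tables."""
    prefix = Path(path_prefix)
    inst_path = prefix.with_name(prefix.name + "_instances.csv")
    if not inst_path.exists():
        raise FileNotFoundError(f"no prior run found at {inst_path}")
    records = records_from_table(pd.read_csv(inst_path))
    contacts = None
    contacts_path = prefix.with_name(prefix.name + "_contacts.csv")
    if contacts_path.exists():
        df = pd.read_csv(contacts_path, dtype={"capillary_ids": str})
        contacts = [
            ContactResult(
                cm_id=int(row["cm_id"]),
                n_contacts=int(row["n_contacts"]),
                cc_per_area=float(row["cc_per_area_um2"]),
                capillary_ids=tuple(
                    int(x)
                    for x in str(row["capillary_ids"]).split(";")
                    if x not in ("", "nan")
                ),
            )
            for _, row in df.iterrows()
        ]
    expressions = None
    expr_path = prefix.with_name(prefix.name + "_expression.csv")
    if expr_path.exists():
        df = pd.read_csv(expr_path)
        expressions = [
            ExpressionResult(cm_id=int(r["cm_id"]), positive_pct=float(r["positive_pct"]))
            for _, r in df.iterrows()
        ]
    return ImageReport(
        image_id=image_id or prefix.name,
        records=records,
        config=config,
        microns_per_pixel=microns_per_pixel,
        contacts=contacts,
        expressions=expressions,
    )


def read_exclusion_file(path: str | Path) -> list[int]:
    """Parse a manual-exclusion list: one instance id per line."""
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        ids.append(int(line))
    return ids


def apply_exclusions(
    report: ImageReport, exclusion_ids: Iterable[int]
) -> ImageReport:
    """Drop manually flagged instances and recompute dependent results.

    Unknown ids produce a logged warning, not a failure (manual lists go
    stale when re-run on corrected outputs).  Contacts and expressions
    referencing excluded cardiomyocytes or capillaries are recomputed from
    the surviving records; the dropped records are kept in the report's
    ``excluded`` audit list.  The operation is idempotent and
    order-independent.
    """
    wanted = set(int(i) for i in exclusion_ids)
    known = {r.instance_id for r in report.records}
    unknown = wanted - known
    if unknown:
        logger.warning(
            "exclusion list references %d unknown instance id(s): %s",
            len(unknown),
            sorted(unknown)[:20],
        )
    kept = [r for r in report.records if r.instance_id not in wanted]
    dropped = [r for r in report.records if r.instance_id in wanted]
    kept_cm = {r.instance_id for r in kept if r.cls == CLASS_CM}
    kept_cap = {r.instance_id for r in kept if r.cls == CLASS_CAPILLARY}

    contacts = None
    if report.contacts is not None:
        # recount each surviving CM's contacts from its stored capillary id
        # set, dropping excluded capillaries — exactly equivalent to a
        # from-scratch distance recomputation on the reduced instance set
        area_by_id = {r.instance_id: r.area_um2 for r in kept}
        contacts = []
        for c in report.contacts:
            if c.cm_id not in kept_cm:
                continue
            caps = tuple(i for i in c.capillary_ids if i in kept_cap)
            area = area_by_id[c.cm_id]
            contacts.append(
                ContactResult(
                    cm_id=c.cm_id,
                    n_contacts=len(caps),
                    cc_per_area=len(caps) / area if area > 0 else 0.0,
                    capillary_ids=caps,
                )
            )
    expressions = None
    if report.expressions is not None:
        expressions = [e for e in report.expressions if e.cm_id in kept_cm]

    return ImageReport(
        image_id=report.image_id,
        records=kept,
        config=report.config,
        microns_per_pixel=report.microns_per_pixel,
        contacts=contacts,
        expressions=expressions,
        excluded=report.excluded + dropped,
    )
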