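#!/usr/bin/env python
"""Convert the published supplementary harmonized-migration workbook into
the frozen CSV schema read by migrisk.

The published workbook (an Excel file accompanying the source study)
holds one row per experimental migration observation. Sheet and column
layouts of supplementary workbooks vary between deposits, so the mapping
from workbook columns to the frozen schema is supplied as a YAML file:

    sheet: "Table S3"
    header_row: 1            # 0-based row index holding the header
    columns:                 # workbook header -> migrisk column
      "CAS": chemical_cas
      "Chemical name": chemical_name
      "Chemical group": chemical_group
      "MW (g/mol)": mw_g_mol
      "log Kow": log_kow
      "Material": material
      "Study": study_id
      "C0 (ug/g)": c0_ug_g
      "Migration rate (ug/10cm2/min)": rate_ug_per_10cm2_min
      "Contact time (min)": contact_time_min
      "Sample area (cm2)": sample_area_cm2
      "Thickness (cm)": sample_thickness_cm
      "In vivo": in_vivo
      "Agitation": agitation

Columns absent from the workbook may be given constants instead:

    defaults:
      sample_thickness_cm: 0.2

Usage:
    python scripts/import_si_workbook.py workbook.xlsx mapping.yaml \
        --out data/si_harmonized.csv

The output is validated by re-reading it through migrisk.read_dataset;
rejected rows are reported with their diagnostics.
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

import pandas as pd
import yaml

from migrisk.dataset import COLUMNS, read_dataset, write_dataset


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__.split("\n")[0])
    ap.add_argument("workbook", type=Path, help="supplementary .xlsx file")
    ap.add_argument("mapping", type=Path, help="column-mapping YAML")
    ap.add_argument("--out", type=Path, default=Path("data/si_harmonized.csv"))
    args = ap.parse_args()

    spec = yaml.safe_load(args.mapping.read_text())
    raw = pd.read_excel(
        args.workbook,
        sheet_name=spec.get("sheet", 0),
        header=int(spec.get("header_row", 0)),
    )
    mapping = spec["columns"]
    missing = [src for src in mapping if src not in raw.columns]
    if missing:
        print(f"workbook is missing mapped columns: {missing}", file=sys.stderr)
        return 1
    df = raw[list(mapping)].rename(columns=mapping)
    for col, value in (spec.get("defaults") or {}).items():
        df[col] = value
    for col in COLUMNS:
        if col not in df.columns:
            df[col] = ""
    args.out.parent.mkdir(parents=True, exist_ok=True)
    write_dataset(df, args.out)

    ds = read_dataset(args.out)
    print(f"wrote {args.out}: {ds.summary()}")
    for d in ds.diagnostics:
        print(f"  rejected row {d.row}: {d.message}", file=sys.stderr)
    return 0 if ds.n_records else 1


if __name__ == "__main__":
    raise SystemExit(main())
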