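"""Rendering of summaries and screens: machine-readable TSV plus markdown.

TSV outputs keep full precision; report tables round to two decimals.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .cohort import DemographicsSummary
from .signals import ScreenResult


def _fmt(x, nd=2):
    if x is None or (isinstance(x, float) and pd.isna(x)):
        return ""
    return f"{x:.{nd}f}" if isinstance(x, float) else str(x)


def _markdown_table(df: pd.DataFrame) -> str:
    header = "| " + " | ".join(map(str, df.columns)) + " |"
    sep = "|" + "|".join("---" for _ in df.columns) + "|"
    body = ["| " + " | ".join(_fmt(v) if isinstance(v, float) else str(v) for v in row) + " |"
            for row in df.itertuples(index=False)]
    return "\n".join([header, sep, *body])


def write_summary(summary: DemographicsSummary, out_dir, stem: str = "summary") -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = summary.to_frame()
    tsv = out_dir / f"{stem}.tsv"
    frame.to_csv(tsv, sep="\t", index=False)
    lines = ["| Section | Label | Count | % |", "|---|---|---:|---:|"]
    for row in frame.itertuples(index=False):
        lines.append(f"| {row.section} | {row.label} | {row.count} | {_fmt(row.percent)} |")
    md = out_dir / f"{stem}.md"
    md.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return {"tsv": tsv, "md": md}


def screen_frame_rounded(result: ScreenResult) -> pd.DataFrame:
    df = result.to_frame()
    pretty = pd.DataFrame({
        "term": df["term"], "level": df["level"], "code": df["code"], "a": df["a"],
        "ROR (95% CI)": [f"{_fmt(r)} ({_fmt(lo)}-{_fmt(hi)})" for r, lo, hi in zip(df["ror"], df["ror_lo"], df["ror_hi"])],
        "PRR (95% CI)": [f"{_fmt(r)} ({_fmt(lo)}-{_fmt(hi)})" for r, lo, hi in zip(df["prr"], df["prr_lo"], df["prr_hi"])],
        "chi2": df["chi2"].round(2),
        "IC (IC-2SD)": [f"{_fmt(i)} ({_fmt(lo)})" for i, lo in zip(df["ic"], df["ic_minus_2sd"])],
        "EBGM (EBGM05)": [f"{_fmt(e)} ({_fmt(lo)})" for e, lo in zip(df["ebgm"], df["ebgm05"])],
        "band": df["band"], "consensus": df["consensus"],
    })
    return pretty


def write_screen(result: ScreenResult, out_dir, stem: str) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / f"{stem}.tsv"
    result.to_frame().to_csv(tsv, sep="\t", index=False)
    pretty = screen_frame_rounded(result)
    lines = [
        f"# Signal screen ({result.level} level)",
        "",
        f"Terms screened (a >= 1): {result.cascade['n_terms']}  ",
        f"Passing ROR and PRR: {result.cascade['ror_prr']}  ",
        f"Passing ROR, PRR and BCPNN: {result.cascade['ror_prr_bcpnn']}  ",
        f"Consensus (all four algorithms): {result.cascade['consensus']}  ",
        f"Unmapped reaction rows: {result.n_unmapped_pts}",
        "",
        _markdown_table(pretty),
    ]
    md = out_dir / f"{stem}.md"
    md.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return {"tsv": tsv, "md": md}


def write_reverse(rows: list, out_dir, stem: str) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for name, s, d in rows:
        records.append({
            "drug": name, "a": s.a,
            "ror": s.ror, "ror_lo": s.ror_lo, "ror_hi": s.ror_hi,
            "prr": s.prr, "prr_lo": s.prr_lo, "prr_hi": s.prr_hi,
            "chi2": s.chi2, "ic": s.ic, "ic_minus_2sd": s.ic_minus_2sd,
            "ebgm": s.ebgm, "ebgm05": s.ebgm05, "band": d.bcpnn_band,
            "consensus": d.consensus,
        })
    df = pd.DataFrame(records)
    tsv = out_dir / f"{stem}.tsv"
    df.to_csv(tsv, sep="\t", index=False)
    return {"tsv": tsv}
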