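"""Readers for the plain-text formats the pipeline consumes.

Every writer in :mod:`hervscape.synthetic` has a matching reader here, and
the pipeline only touches files through these functions, so synthetic and
real inputs travel the same code path.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from cyvcf2 import VCF


def read_counts(path: Path | str) -> pd.DataFrame:
    """Transcript x sample integer count matrix from TSV."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_library_sizes(path: Path | str) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].rename("library_size")


def read_panel(path: Path | str) -> list[str]:
    """One transcript id per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_profiles(path: Path | str) -> pd.DataFrame:
    """Gene x column expression profiles (purified cells or backgrounds)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_msi_sites(path: Path | str) -> pd.DataFrame:
    """Microsatellite candidate catalog from the extended BED.

    Columns: chrom, start, end (0-based half-open), site_id, repeat length
    as the score, strand, a coding/noncoding annotation and the repeat unit.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "site_id",
                            "ref_repeat_length", "strand", "annotation",
                            "repeat_unit"],
                     dtype={"chrom": str})
    df["noncoding"] = df["annotation"] == "noncoding"
    return df[["site_id", "chrom", "start", "end", "repeat_unit",
               "ref_repeat_length", "noncoding"]]


def read_msi_histograms(path: Path | str) -> pd.DataFrame:
    """Long-format read-length histograms: site_id, sample_id, length, count."""
    return pd.read_csv(path, sep="\t",
                       dtype={"site_id": str, "sample_id": str})


def read_variants_vcf(path: Path | str) -> pd.DataFrame:
    """Somatic variant table from a VCF with DP/AD/VAF/STRANDS INFO keys."""
    rows = []
    for v in VCF(str(path)):
        info = dict(v.INFO)
        rows.append({
            "sample_id": info.get("SAMPLE", ""),
            "chrom": v.CHROM,
            "pos": v.POS,
            "ref": v.REF,
            "alt": v.ALT[0] if v.ALT else "",
            "vaf_tumor": float(info.get("VAF_T", float("nan"))),
            "vaf_normal": float(info.get("VAF_N", float("nan"))),
            "dp_tumor": int(info.get("DP_T", 0)),
            "dp_normal": int(info.get("DP_N", 0)),
            "ad_tumor": int(info.get("AD_T", 0)),
            "both_strands": int(info.get("STRANDS", 2)) >= 2,
            "gene": info.get("GENE", "") or "",
            "aa_change": info.get("AA", "") or "",
            "pathogenic": bool(info.get("PATH", False)),
        })
    return pd.DataFrame(rows)


def read_cn_calls(path: Path | str) -> tuple[pd.DataFrame, pd.Series]:
    """Gene-level CN calls; returns (calls genes x samples, arm per gene)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    arms = df.pop("arm")
    return df, arms


def read_clinical(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def read_truth(path: Path | str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
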