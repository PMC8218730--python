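#!/usr/bin/env python
"""Optional helper: download the deposited datasets from GEO.

Fetches the RNA-seq counts of sorted lymph-node macrophage subsets
(GSE174524) and the legacy microarray comparison series (GSE15767) so the
real-data numbers (gene counts after filtering, platform intersection size,
cross-platform correlation) can be reproduced manually. Requires network
access; nothing in the package or the test suite depends on this script.

Usage:
    python scripts/fetch_geo.py --out data/geo
"""

from __future__ import annotations

import argparse
import gzip
import shutil
import urllib.request
from pathlib import Path

SOURCES = {
    "GSE174524": (
        "https://ftp.ncbi.nlm.nih.gov/geo/series/GSE174nnn/GSE174524/suppl/",
        "RNA-seq supplementary count matrices"),
    "GSE15767": (
        "https://ftp.ncbi.nlm.nih.gov/geo/series/GSE15nnn/GSE15767/matrix/"
        "GSE15767_series_matrix.txt.gz",
        "microarray series matrix"),
}


def fetch(url: str, dest: Path) -> None:
    print(f"downloading {url} -> {dest}")
    with urllib.request.urlopen(url) as resp, open(dest, "wb") as fh:
        shutil.copyfileobj(resp, fh)
    if dest.suffix == ".gz":
        with gzip.open(dest, "rb") as src, open(dest.with_suffix(""), "wb") as out:
            shutil.copyfileobj(src, out)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=str, default="data/geo")
    args = parser.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    url, desc = SOURCES["GSE15767"]
    fetch(url, out / "GSE15767_series_matrix.txt.gz")

    url, desc = SOURCES["GSE174524"]
    print(f"GSE174524 ({desc}): list the supplementary files under\n  {url}\n"
          "and download the gene-level count matrix; save it as TSV with\n"
          "gene ids in the first column to use with "
          "`lnmacs filter` / `lnmacs de`.")


if __name__ == "__main__":
    main()
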