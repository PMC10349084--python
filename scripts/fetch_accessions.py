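#!/usr/bin/env python
"""Optional network check against the reference DMSP lyases.

Fetches the *E. huxleyi* Alma1 (AKO62592) and *Symbiodinium* Sym-Alma
(P0DN22) protein sequences from NCBI, reports the canonical cysteine
contexts on Alma1 (expected: N-site at C108, C-site at C265), and, if
``mafft`` is on PATH, aligns the pair and prints percent identity under
both denominator conventions (~26% is expected for this pair).

Requires internet access; nothing else in the package depends on it.

Usage:
    python scripts/fetch_accessions.py [--email you@example.org]
"""

from __future__ import annotations

import argparse
import shutil
import subprocess
import sys
import tempfile
import urllib.parse
import urllib.request
from pathlib import Path

from dlhscan.seq_core import (
    Site,
    find_cysteine_contexts,
    pairwise_identity,
    read_fasta,
    write_fasta,
)

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


def fetch_fasta(accessions: list[str], dest: Path, email: str | None) -> None:
    params = {
        "db": "protein",
        "id": ",".join(accessions),
        "rettype": "fasta",
        "retmode": "text",
    }
    if email:
        params["email"] = email
    url = EFETCH + "?" + urllib.parse.urlencode(params)
    with urllib.request.urlopen(url, timeout=60) as resp:
        dest.write_bytes(resp.read())


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--email", default=None, help="Contact email for NCBI E-utilities.")
    args = ap.parse_args()

    with tempfile.TemporaryDirectory() as tmp:
        raw = Path(tmp) / "refs.faa"
        fetch_fasta(["AKO62592", "P0DN22"], raw, args.email)
        records = read_fasta(raw)
        by_acc = {r.id.split(".")[0]: r for r in records}
        alma1 = by_acc["AKO62592"]
        sym = by_acc["P0DN22"]

        hits = find_cysteine_contexts(alma1)
        print("Alma1 (AKO62592) cysteine contexts:")
        for h in hits:
            print(f"  {h.site.value} {h.context} at C{h.c_position}")
        n_ok = any(h.site is Site.N_SITE and h.c_position == 108 for h in hits)
        c_ok = any(h.site is Site.C_SITE and h.c_position == 265 for h in hits)
        print(f"  N-site at C108: {'yes' if n_ok else 'NO'}")
        print(f"  C-site at C265: {'yes' if c_ok else 'NO'}")

        if shutil.which("mafft") is None:
            print("mafft not found; skipping the pairwise identity check")
            return 0
        pair = Path(tmp) / "pair.faa"
        aligned = Path(tmp) / "pair.afa"
        write_fasta([alma1, sym], pair)
        with open(aligned, "w") as fh:
            subprocess.run(
                ["mafft", "--quiet", str(pair)], stdout=fh, check=True
            )
        aln = read_fasta(aligned, aligned=True)
        a, b = aln.records
        for scope in ("aligned_columns", "shorter_sequence"):
            ident = pairwise_identity(a, b, scope=scope)
            print(f"Alma1 vs Sym-Alma identity ({scope}): {ident:.1f}%")
    return 0


if __name__ == "__main__":
    sys.exit(main())
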