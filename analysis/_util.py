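"""Shared paths and a tiny TSV writer for the analysis drivers."""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
# bulky regenerable trajectory data lives outside the results tables
DATA = ROOT / "scratch" / "data"


def tsv(path, header, rows):
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(f"{v:.8g}" if isinstance(v, float) else str(v)
                               for v in row) + "\n")
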