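"""Flat-file I/O helpers: minimal VCF 4.2 records and provenance headers.

The pipeline's VCF needs are deliberately flat — site records with INFO
key=value pairs and a FILTER column listing violated rule names — so a
small dedicated writer keeps outputs byte-reproducible and easy to diff.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

from . import __version__


@dataclass
class VcfRecord:
    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    qual: float | None = None
    filters: tuple[str, ...] = ()  # empty = PASS
    info: dict = field(default_factory=dict)
    id: str = "."


def _fmt_info(info: dict) -> str:
    if not info:
        return "."
    return ";".join(f"{k}={v}" for k, v in info.items())


def provenance_lines(seed=None, config=None, comment_char="##") -> list[str]:
    """Header comment lines carrying tool version, config hash, and seed."""
    lines = [f"{comment_char}spudsnp_version={__version__}"]
    if seed is not None:
        lines.append(f"{comment_char}spudsnp_seed={seed}")
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        lines.append(f"{comment_char}spudsnp_config_hash={digest}")
    return lines


def write_vcf(path, records, extra_header=(), seed=None, config=None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for line in provenance_lines(seed=seed, config=config):
            fh.write(line + "\n")
        for line in extra_header:
            fh.write(line.rstrip("\n") + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            alt = ",".join(r.alts) if r.alts else "."
            qual = "." if r.qual is None else f"{r.qual:g}"
            filt = "PASS" if not r.filters else ";".join(r.filters)
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.id}\t{r.ref}\t{alt}\t{qual}\t{filt}\t"
                f"{_fmt_info(r.info)}\n"
            )


def read_vcf(path) -> list[VcfRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            info = {}
            if f[7] != ".":
                for kv in f[7].split(";"):
                    k, _, v = kv.partition("=")
                    info[k] = v
            records.append(
                VcfRecord(
                    chrom=f[0],
                    pos=int(f[1]),
                    id=f[2],
                    ref=f[3],
                    alts=tuple(f[4].split(",")) if f[4] != "." else (),
                    qual=None if f[5] == "." else float(f[5]),
                    filters=() if f[6] in ("PASS", ".") else tuple(f[6].split(";")),
                    info=info,
                )
            )
    return records
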