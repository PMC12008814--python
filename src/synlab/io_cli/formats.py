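"""Readers/writers for the plain-text interchange formats.

All coordinates are 0-based, half-open (BED convention); every written file
carries a header comment declaring this.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from ..core import Motif, MotifInstance, StrandedProfile
from ..seqs import SequenceError

COORD_HEADER = "# coordinates: 0-based, half-open"


class FormatError(ValueError):
    pass


# ------------------------------------------------------------------- FASTA
def write_fasta(path, sequences: Dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path, allow_n: bool = True) -> Dict[str, str]:
    """Parse FASTA; upper-cases sequences; rejects non-ACGTN characters and
    duplicate contig names."""
    sequences: Dict[str, str] = {}
    name: Optional[str] = None
    chunks: List[str] = []
    allowed = set("ACGT" + ("N" if allow_n else ""))

    def flush():
        if name is None:
            return
        seq = "".join(chunks).upper()
        for i, c in enumerate(seq):
            if c not in allowed:
                raise SequenceError(f"contig {name!r}: invalid character {c!r} "
                                    f"at position {i}")
        if name in sequences:
            raise FormatError(f"duplicate contig name {name!r}")
        sequences[name] = seq

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
                chunks = []
            elif line and not line.startswith(";"):
                chunks.append(line.strip())
    flush()
    if name is None and not sequences:
        raise FormatError(f"{path}: no FASTA records")
    return sequences


# --------------------------------------------------------------------- BED
def write_instances_bed(path, instances: Sequence[MotifInstance]) -> None:
    """BED6+3: name=motif, score=int, strand + (motif_name, total_contribution,
    source); sorted by (contig, start) on write."""
    insts = sorted(instances, key=lambda i: (i.contig, i.start, i.end))
    scores = [i.total_contribution if i.total_contribution is not None
              else i.match_score for i in insts]
    peak = max((abs(s) for s in scores), default=1.0) or 1.0
    with open(path, "w") as fh:
        fh.write(COORD_HEADER + "\n")
        for inst, s in zip(insts, scores):
            bed_score = int(round(1000 * abs(s) / peak))
            tc = "" if inst.total_contribution is None else f"{inst.total_contribution:.6g}"
            fh.write("\t".join([
                inst.contig, str(inst.start), str(inst.end), inst.motif_name,
                str(bed_score), inst.strand, inst.motif_name, tc, inst.source,
            ]) + "\n")


def read_instances_bed(path, contig_lengths: Optional[Dict[str, int]] = None
                       ) -> List[MotifInstance]:
    out: List[MotifInstance] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{ln}: expected >= 6 tab-separated columns")
            contig, start, end, name, _score, strand = fields[:6]
            start, end = int(start), int(end)
            if end <= start:
                raise FormatError(f"{path}:{ln}: end <= start")
            if strand not in "+-":
                raise FormatError(f"{path}:{ln}: invalid strand {strand!r}")
            if contig_lengths is not None and contig in contig_lengths and \
                    end > contig_lengths[contig]:
                raise FormatError(f"{path}:{ln}: interval beyond contig end")
            motif_name = fields[6] if len(fields) > 6 else name
            tc = None
            if len(fields) > 7 and fields[7]:
                tc = float(fields[7])
            source = fields[8] if len(fields) > 8 else "planted"
            out.append(MotifInstance(contig, start, end, strand, motif_name,
                                     total_contribution=tc, source=source))
    out.sort(key=lambda i: (i.contig, i.start, i.end))
    return out


def write_truth_bed(path, genome) -> None:
    """Truth annotation: BED6+2 (motif_name, occupancy)."""
    insts = sorted(genome.truth, key=lambda i: (i.contig, i.start))
    peak = max((i.occupancy or 0.0 for i in insts), default=1.0) or 1.0
    with open(path, "w") as fh:
        fh.write(COORD_HEADER + "\n")
        for i in insts:
            occ = i.occupancy or 0.0
            fh.write("\t".join([
                i.contig, str(i.start), str(i.end), i.motif_name,
                str(int(round(1000 * occ / peak))), i.strand,
                i.motif_name, f"{occ:.6g}",
            ]) + "\n")


# ---------------------------------------------------------------- bedGraph
def write_bedgraph(path, profiles: Dict[str, StrandedProfile], strand: str) -> None:
    arr_of = {"+": (lambda p: p.plus), "-": (lambda p: p.minus)}[strand]
    with open(path, "w") as fh:
        fh.write(COORD_HEADER + "\n")
        for contig in sorted(profiles):
            prof = profiles[contig]
            vals = arr_of(prof)
            # run-length encode constant stretches
            start = 0
            for i in range(1, len(vals) + 1):
                if i == len(vals) or vals[i] != vals[start]:
                    if vals[start] != 0:
                        fh.write(f"{contig}\t{prof.start + start}\t{prof.start + i}"
                                 f"\t{vals[start]:.6g}\n")
                    start = i


def read_bedgraph(path, contig_lengths: Dict[str, int], task: str,
                  strand_files: Optional[Tuple[str, str]] = None
                  ) -> Dict[str, np.ndarray]:
    arrays = {c: np.zeros(n) for c, n in contig_lengths.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            contig, s, e, v = line.split("\t")
            if contig in arrays:
                arrays[contig][int(s):int(e)] = float(v)
    return arrays


# -------------------------------------------------------------- MEME motifs
def write_meme(path, motifs: Sequence[Motif],
               background: Sequence[float] = (0.25, 0.25, 0.25, 0.25)) -> None:
    """MEME minimal motif format for the frequency PWMs."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*background))
        for m in motifs:
            fh.write(f"MOTIF {m.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.width} "
                     f"nsites= {max(m.support, 1)} E= 0\n")
            for col in m.pwm.T:
                fh.write(" " + "  ".join(f"{x:.6f}" for x in col) + "\n")
            fh.write("\n")


def read_meme(path) -> List[Motif]:
    motifs: List[Motif] = []
    name = None
    rows: List[List[float]] = []
    expect = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                name = line.split()[1]
            elif line.startswith("letter-probability matrix"):
                toks = line.split()
                expect = int(toks[toks.index("w=") + 1])
                rows = []
            elif name is not None and expect and line and \
                    (line[0].isdigit() or line[0] == "."):
                rows.append([float(x) for x in line.split()])
                if len(rows) == expect:
                    pwm = np.asarray(rows).T
                    pwm = pwm / pwm.sum(axis=0)
                    cwm = np.log2(np.maximum(pwm, 1e-4) / 0.25)
                    motifs.append(Motif(name, pwm, cwm))
                    name, rows, expect = None, [], 0
    return motifs


# --------------------------------------------------------------- CWM sidecar
def write_cwm_json(path, motifs: Sequence[Motif]) -> None:
    data = [{"name": m.name, "cwm": m.cwm.tolist(), "pwm": m.pwm.tolist(),
             "consensus": m.consensus, "support": m.support} for m in motifs]
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def read_cwm_json(path) -> List[Motif]:
    with open(path) as fh:
        data = json.load(fh)
    return [Motif(d["name"], np.asarray(d["pwm"]), np.asarray(d["cwm"]),
                  consensus=d.get("consensus", ""), support=d.get("support", 0))
            for d in data]


# ------------------------------------------------------------------ islands
def write_islands(path, islands) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_HEADER + "\n")
        for k, isl in enumerate(islands):
            fh.write(f"{isl.contig}\t{isl.start}\t{isl.end}\tisland_{k + 1}\n")


def write_profiles_hdf5(path, profiles: Dict[str, Dict[str, StrandedProfile]]) -> None:
    """Optional HDF5 container: /task/strand/contig datasets (requires h5py)."""
    import h5py

    with h5py.File(path, "w") as fh:
        for task, per_contig in profiles.items():
            for contig, prof in per_contig.items():
                fh.create_dataset(f"{task}/plus/{contig}", data=prof.plus)
                fh.create_dataset(f"{task}/minus/{contig}", data=prof.minus)
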