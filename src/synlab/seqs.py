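"""Shared DNA sequence utilities: encoding, reverse complement, shuffles, IUPAC."""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}
_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class SequenceError(ValueError):
    """Raised for sequences containing characters outside the expected alphabet."""


def validate_acgt(seq: str, *, name: str = "sequence") -> str:
    seq = seq.upper()
    for i, b in enumerate(seq):
        if b not in BASE_INDEX:
            raise SequenceError(f"{name}: invalid base {b!r} at position {i}")
    return seq


def revcomp(seq: str) -> str:
    return seq.upper().translate(COMPLEMENT)[::-1]


def revcomp_iupac(pattern: str) -> str:
    return pattern.upper().translate(_IUPAC_COMPLEMENT)[::-1]


def one_hot(seq: str, dtype=np.float32) -> np.ndarray:
    """Encode a DNA string as a (4, L) one-hot matrix in ACGT row order."""
    idx = encode(seq)
    x = np.zeros((4, len(seq)), dtype=dtype)
    x[idx, np.arange(len(seq))] = 1.0
    return x


def encode(seq: str) -> np.ndarray:
    """Integer-encode (A=0, C=1, G=2, T=3)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, i in BASE_INDEX.items():
        out[arr == ord(base)] = i
    if (out < 0).any():
        bad = int(np.argmax(out < 0))
        raise SequenceError(f"invalid base {seq[bad]!r} at position {bad}")
    return out


def decode(idx: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in idx)


def random_sequence(length: int, rng: np.random.Generator, gc: float = 0.42) -> str:
    """IID background sequence at the given GC fraction."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return decode(rng.choice(4, size=length, p=p))


def iupac_onehot_mask(pattern: str) -> np.ndarray:
    """(4, W) boolean mask: True where the base is allowed by the IUPAC code."""
    mask = np.zeros((4, len(pattern)), dtype=bool)
    for j, code in enumerate(pattern.upper()):
        try:
            allowed = IUPAC[code]
        except KeyError:
            raise SequenceError(f"invalid IUPAC code {code!r} at position {j}") from None
        for b in allowed:
            mask[BASE_INDEX[b], j] = True
    return mask


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving exact dinucleotide counts (Altschul-Erickson).

    Builds the dinucleotide multigraph, draws a uniform-ish Eulerian path by
    shuffling each vertex's out-edge list while keeping a spanning arborescence
    into the terminal vertex, then walks the path.
    """
    seq = seq.upper()
    if len(seq) < 3:
        return seq
    bases = sorted(set(seq))
    edges = {b: [] for b in bases}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    # pick, for every non-terminal vertex, a final out-edge lying on a tree to `last`
    for _attempt in range(100):
        tree_edge = {}
        ok = True
        for v in bases:
            if v == last:
                continue
            if not edges[v]:
                ok = False
                break
            tree_edge[v] = edges[v][int(rng.integers(len(edges[v])))]
        if not ok:
            break
        # check connectivity of chosen edges toward `last`
        good = True
        for v in tree_edge:
            seen = set()
            u = v
            while u != last:
                if u in seen or u not in tree_edge:
                    good = False
                    break
                seen.add(u)
                u = tree_edge[u]
            if not good:
                break
        if good:
            shuffled = {}
            for v in bases:
                rest = list(edges[v])
                if v != last:
                    rest.remove(tree_edge[v])
                rng.shuffle(rest)
                if v != last:
                    rest.append(tree_edge[v])
                shuffled[v] = rest
            out = [seq[0]]
            ptr = {b: 0 for b in bases}
            v = seq[0]
            for _ in range(len(seq) - 1):
                nxt = shuffled[v][ptr[v]]
                ptr[v] += 1
                out.append(nxt)
                v = nxt
            return "".join(out)
    return seq  # degenerate composition: return unchanged
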