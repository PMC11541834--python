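"""SMILES tokenization, vocabularies, directional sequence encoding and
molecule identity keys.

The tokenizer treats two-character halogens (``Cl``, ``Br``), bracket atoms
(``[nH]``, ``[*]``, ...) and two-digit ring closures (``%NN``) as single
tokens; every other character is its own token.  Detokenization is plain
concatenation, so ``detokenize(tokenize(s)) == s`` for any tokenizable string.

Sequences can be encoded left-to-right or right-to-left (token order is
reversed, tokens themselves are never reversed), mirroring the idea that a
SMILES string can be grown from either end.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

PAD, START, END, UNK = "<pad>", "<start>", "<end>", "<unk>"
ATTACHMENT = "[*]"
RESERVED = (PAD, START, END, UNK, ATTACHMENT)

_TOKEN_RE = re.compile(r"(\[[^\]]*\]|Cl|Br|%\d\d|.)")


class TokenizationError(ValueError):
    """Raised for strings that cannot be split into SMILES tokens."""


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into tokens.

    Raises :class:`TokenizationError` on empty input or unbalanced square
    brackets.
    """
    if not smiles:
        raise TokenizationError("empty SMILES string")
    depth = 0
    for ch in smiles:
        if ch == "[":
            depth += 1
            if depth > 1:
                raise TokenizationError(f"nested '[' in {smiles!r}")
        elif ch == "]":
            depth -= 1
            if depth < 0:
                raise TokenizationError(f"unmatched ']' in {smiles!r}")
    if depth != 0:
        raise TokenizationError(f"unbalanced brackets in {smiles!r}")
    return _TOKEN_RE.findall(smiles)


def detokenize(tokens: Iterable[str]) -> str:
    return "".join(tokens)


@dataclass(frozen=True)
class Vocabulary:
    """Token-to-index map with reserved control tokens.

    Indices are contiguous from 0; the reserved tokens (PAD, START, END, UNK
    and the attachment point ``[*]``) occupy the first five slots, followed by
    the corpus tokens in sorted order, so identical corpora give identical
    vocabularies.
    """

    token_to_index: dict[str, int]
    index_to_token: tuple[str, ...] = field(default=())

    def __post_init__(self):
        object.__setattr__(
            self,
            "index_to_token",
            tuple(t for t, _ in sorted(self.token_to_index.items(), key=lambda kv: kv[1])),
        )

    def __len__(self) -> int:
        return len(self.token_to_index)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_index

    @property
    def pad(self) -> int:
        return self.token_to_index[PAD]

    @property
    def start(self) -> int:
        return self.token_to_index[START]

    @property
    def end(self) -> int:
        return self.token_to_index[END]

    @property
    def unk(self) -> int:
        return self.token_to_index[UNK]

    @classmethod
    def from_corpus(cls, corpus: Iterable[str]) -> "Vocabulary":
        corpus = list(corpus)
        if not corpus:
            raise ValueError("empty corpus")
        tokens: set[str] = set()
        for s in corpus:
            tokens.update(tokenize(s))
        ordered = list(RESERVED) + sorted(tokens - set(RESERVED))
        return cls({t: i for i, t in enumerate(ordered)})

    def encode(self, smiles: str, direction: str = "ltr", max_length: int | None = None) -> list[int]:
        """Encode a SMILES string as START + token indices + END.

        ``direction`` is ``"ltr"`` or ``"rtl"``; right-to-left reverses token
        order.  Unknown tokens map to UNK.  ``max_length`` bounds the total
        encoded length (including START/END).
        """
        toks = tokenize(smiles)
        if direction == "rtl":
            toks = toks[::-1]
        elif direction != "ltr":
            raise ValueError(f"direction must be 'ltr' or 'rtl', got {direction!r}")
        idx = [self.start] + [self.token_to_index.get(t, self.unk) for t in toks] + [self.end]
        if max_length is not None and len(idx) > max_length:
            raise ValueError(f"encoded length {len(idx)} exceeds max_length {max_length}")
        return idx

    def decode(self, indices: Sequence[int], direction: str = "ltr") -> str:
        """Invert :meth:`encode`, stripping control tokens."""
        toks = []
        for i in indices:
            t = self.index_to_token[i]
            if t in (START, PAD):
                continue
            if t == END:
                break
            toks.append(t)
        if direction == "rtl":
            toks = toks[::-1]
        return detokenize(toks)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.index_to_token:
                fh.write(t + "\n")

    @classmethod
    def load(cls, path) -> "Vocabulary":
        with open(path) as fh:
            tokens = [line.rstrip("\n") for line in fh if line.rstrip("\n")]
        return cls({t: i for i, t in enumerate(tokens)})


def build_vocab(corpus: Iterable[str]) -> Vocabulary:
    """Build a :class:`Vocabulary` over a SMILES corpus."""
    return Vocabulary.from_corpus(corpus)


def dedup_key(smiles: str) -> str:
    """Identity key for a molecule: its standard InChI.

    Two SMILES spellings of the same molecule give equal keys; invalid SMILES
    raise ``ValueError``.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    inchi = Chem.MolToInchi(mol)
    if not inchi:
        raise ValueError(f"InChI generation failed for {smiles!r}")
    return inchi


def canonical(smiles: str) -> str:
    """Canonical SMILES, raising on parse failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)
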