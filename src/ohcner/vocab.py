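"""Character vocabulary with reserved PAD (0) and UNK (1) ids.

Serialized as one character per line; the line number is the id, and the
first two lines hold the literal ``<pad>`` / ``<unk>`` tokens.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

PAD, UNK = "<pad>", "<unk>"
PAD_ID, UNK_ID = 0, 1


class Vocab:
    def __init__(self, chars: Sequence[str] = ()):
        self.itos: list[str] = [PAD, UNK]
        self.stoi: dict[str, int] = {PAD: 0, UNK: 1}
        for ch in chars:
            self.add(ch)

    def add(self, ch: str) -> int:
        if ch not in self.stoi:
            self.stoi[ch] = len(self.itos)
            self.itos.append(ch)
        return self.stoi[ch]

    def __len__(self) -> int:
        return len(self.itos)

    def __contains__(self, ch: str) -> bool:
        return ch in self.stoi

    def encode(self, text: Iterable[str]) -> list[int]:
        return [self.stoi.get(ch, UNK_ID) for ch in text]

    def decode(self, ids: Iterable[int]) -> list[str]:
        return [self.itos[i] for i in ids]

    @classmethod
    def build(cls, texts: Iterable[str]) -> "Vocab":
        v = cls()
        for text in texts:
            for ch in text:
                v.add(ch)
        return v

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for ch in self.itos:
                fh.write(ch + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocab":
        with open(path, encoding="utf-8") as fh:
            lines = [line.rstrip("\n") for line in fh]
        if lines[:2] != [PAD, UNK]:
            raise ValueError("vocabulary file must reserve ids 0/1 for <pad>/<unk>")
        v = cls()
        for ch in lines[2:]:
            v.add(ch)
        return v
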