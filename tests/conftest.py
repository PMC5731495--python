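from __future__ import annotations

import random

import pytest

from dbgmerge.io_formats import SeqRecord


def random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def random_records(rng: random.Random, n: int, min_len: int, max_len: int) -> list[SeqRecord]:
    return [SeqRecord(f"s{i}", random_seq(rng, rng.randint(min_len, max_len))) for i in range(n)]


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)
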