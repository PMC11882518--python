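import random

import pytest

from bamir.io_formats import SequenceRecord, reverse_complement


@pytest.fixture(scope="session")
def mirna():
    return SequenceRecord("mir-x", "AGCAUUAACGGUCAAGCUUU")


@pytest.fixture(scope="session")
def toy_dataset(tmp_path_factory):
    """One shared toy dataset directory with its planted truth."""
    from bamir.datasets import simulate_dataset

    out = tmp_path_factory.mktemp("toy")
    truth = simulate_dataset(out, seed=3)
    return out, truth


def oracle_classify(mirna: SequenceRecord, window: str) -> str | None:
    """Independent string-pattern oracle for seed-site classification.

    Builds the exact reverse-complement patterns of each class and
    compares substrings, rather than checking pairing per position.
    """
    m = mirna.sequence
    seed7 = reverse_complement(m[1:8])
    core6 = reverse_complement(m[1:7])
    off6 = reverse_complement(m[2:8])
    if window[:7] == seed7:
        return "8mer" if window[7] == "A" else "7mer-m8"
    if window[1:7] == core6:
        return "7mer-A1" if window[7] == "A" else "6mer"
    if window[:6] == off6:
        return "off-6mer"
    return None


def oracle_hairpin_loops(dot_bracket: str) -> int:
    """Pair-list oracle: count pairs enclosing no other pair."""
    stack, pairs = [], []
    for i, ch in enumerate(dot_bracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            pairs.append((stack.pop(), i))
    return sum(
        1
        for (i, j) in pairs
        if not any(i < k < l < j for (k, l) in pairs if (k, l) != (i, j))
    )


def random_dot_bracket(rng: random.Random, max_len: int = 40) -> str:
    """A random balanced dot-bracket string."""
    out, depth = [], 0
    n = rng.randint(2, max_len)
    for _ in range(n):
        move = rng.choice("(.)") if depth > 0 else rng.choice("(.")
        if move == "(":
            depth += 1
        elif move == ")":
            depth -= 1
        out.append(move)
    out.extend(")" * depth)
    return "".join(out)
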