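import numpy as np
import pytest

from fbmeta.quantify import compute_tpm
from fbmeta.synthetic_data import default_spec, generate


@pytest.fixture(scope="session")
def small_bundle():
    """A compact default community shared by read-only tests."""
    return generate(default_spec(depth=20_000), 4, 4, seed=11)


@pytest.fixture(scope="session")
def small_tpm(small_bundle):
    lengths = small_bundle.lengths()
    return (
        compute_tpm(small_bundle.mg, lengths),
        compute_tpm(small_bundle.mt, lengths),
    )


@pytest.fixture(scope="session")
def bundle_dir(small_bundle, tmp_path_factory):
    from fbmeta.synthetic_data import write_bundle

    out = tmp_path_factory.mktemp("bundle")
    return write_bundle(small_bundle, out)


# ---------------------------------------------------------------------------
# Independent oracle machinery for module-logic tests.  The test-local AST,
# its renderer and its evaluator deliberately share no code with the package.


def random_module_ast(rng: np.random.Generator, max_kos: int = 8, max_depth: int = 3):
    """Random expression as a test-local nested-tuple AST."""
    pool = sorted({f"K{int(rng.integers(0, 100000)):05d}" for _ in range(max_kos)})

    def ko():
        return ("ko", pool[int(rng.integers(len(pool)))])

    def atom(depth):
        r = rng.random()
        if r < 0.05:
            return ("wc",)
        if depth <= 0 or r < 0.55:
            return ko()
        return group(depth - 1)

    def cpx(depth):
        n = int(rng.integers(2, 4))
        members = []
        for _ in range(n):
            child = atom(depth)
            if rng.random() < 0.2:
                child = ("opt", child)
            members.append(child)
        return ("cpx", members)

    def alt(depth):
        r = rng.random()
        if r < 0.3 and depth > 0:
            return cpx(depth - 1)
        return atom(depth)

    def step(depth):
        if rng.random() < 0.4:
            n = int(rng.integers(2, 4))
            return ("or", [alt(depth) for _ in range(n)])
        return alt(depth)

    def group(depth):
        n = int(rng.integers(1, 4))
        steps = []
        for _ in range(n):
            s = step(depth)
            if rng.random() < 0.1:
                s = ("opt", s)
            steps.append(s)
        return ("and", steps) if len(steps) > 1 else steps[0]

    return group(max_depth), pool


def render_module_ast(node) -> str:
    """Serialize the test-local AST to a DEFINITION string."""
    kind = node[0]
    if kind == "ko":
        return node[1]
    if kind == "wc":
        return "--"
    if kind == "opt":
        return "-" + _render_optional(node[1])
    if kind == "cpx":
        parts = []
        for i, child in enumerate(node[1]):
            if child[0] == "opt":
                parts.append("-" + _render_optional(child[1]))
            else:
                parts.append(("+" if i else "") + _render_tight(child))
        return "".join(parts)
    if kind == "or":
        alts = [
            "(" + render_module_ast(c) + ")" if c[0] == "and" else render_module_ast(c)
            for c in node[1]
        ]
        return "(" + ",".join(alts) + ")"
    if kind == "and":
        return " ".join(
            "(" + render_module_ast(c) + ")" if c[0] == "and" else render_module_ast(c)
            for c in node[1]
        )
    raise ValueError(kind)


def _render_tight(node) -> str:
    # complex members must be atoms: parenthesize anything structured
    if node[0] in ("ko", "wc"):
        return render_module_ast(node)
    return "(" + render_module_ast(node) + ")"


def _render_optional(node) -> str:
    # "-" + "--" would retokenize as "--" "-"; keep wildcards parenthesized
    if node[0] == "ko":
        return node[1]
    return "(" + render_module_ast(node) + ")"


def eval_module_ast(node, present: set, wildcard: bool = True) -> bool:
    """Truth-table oracle over the test-local AST."""
    kind = node[0]
    if kind == "ko":
        return node[1] in present
    if kind == "wc":
        return wildcard
    if kind == "opt":
        return True
    if kind in ("and", "cpx"):
        return all(eval_module_ast(c, present, wildcard) for c in node[1])
    if kind == "or":
        return any(eval_module_ast(c, present, wildcard) for c in node[1])
    raise ValueError(kind)


def ast_kos(node) -> set:
    kind = node[0]
    if kind == "ko":
        return {node[1]}
    if kind == "wc":
        return set()
    if kind == "opt":
        return ast_kos(node[1])
    return set().union(*(ast_kos(c) for c in node[1]))


# ---------------------------------------------------------------------------
# Independent oracle for best-hit taxonomy.


def random_hit_table(rng: np.random.Generator, with_ties: bool = True):
    """Random BLAST hits with occasional engineered bitscore/evalue ties."""
    from fbmeta.io_formats import BlastHit

    n_genes = int(rng.integers(1, 6))
    subjects = [f"s{j}" for j in range(6)]
    hits = []
    for i in range(n_genes):
        gene = f"g{i}"
        n_hits = int(rng.integers(1, 5))
        for _ in range(n_hits):
            bits = float(np.round(rng.choice([50.0, 100.0, 100.0, 200.5, rng.uniform(10, 300)]), 1))
            ev = float(rng.choice([1e-10, 1e-10, 1e-5, 10 ** -rng.uniform(2, 80)]))
            hits.append(
                BlastHit(gene, subjects[int(rng.integers(len(subjects)))], 90.0,
                         100, 1, 0, 1, 100, 1, 100, ev, bits)
            )
        if with_ties and rng.random() < 0.5:
            # exact duplicate score on two different subjects
            hits.append(BlastHit(gene, "s_tie_b", 90.0, 100, 1, 0, 1, 100, 1, 100, 1e-10, 100.0))
            hits.append(BlastHit(gene, "s_tie_a", 90.0, 100, 1, 0, 1, 100, 1, 100, 1e-10, 100.0))
    return hits


def best_hit_oracle(hits):
    """Exhaustive scan: per gene the (max bitscore, min evalue, min subject) hit."""
    genes = {h.query_id for h in hits}
    out = {}
    for gene in genes:
        best = None
        for h in hits:
            if h.query_id != gene:
                continue
            if best is None:
                best = h
            elif h.bitscore != best.bitscore:
                if h.bitscore > best.bitscore:
                    best = h
            elif h.evalue != best.evalue:
                if h.evalue < best.evalue:
                    best = h
            elif h.subject_id < best.subject_id:
                best = h
        out[gene] = best.subject_id
    return out
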