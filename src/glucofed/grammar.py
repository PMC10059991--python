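"""BNF grammars and codon-based genotype-to-phenotype mapping.

Grammatical Evolution separates the search space (variable-length
integer "codon" strings) from the solution space (expressions generated
by a context-free grammar).  Mapping walks the leftmost derivation: each
time a nonterminal with m alternative productions is expanded, one codon
c is consumed and production ``c mod m`` is chosen, so production order
matters and is preserved exactly as written.  If the codon string is
exhausted the read head wraps around (up to ``max_wraps`` times); a
derivation that still has open nonterminals after that is *invalid* —
invalidity is a value, not an exception, and invalid individuals simply
get the worst fitness.

The bundled glucose grammar generates exactly the four-block forecast
shape

    Ghat(t + h*dt) = (Gamma(g...) - Theta(i...) + Omega(c...)) <> Phi(dg...)

with ``<>`` one of {+, -, *}: a glucose-history block, minus an
insulin-lead block, plus a carbohydrate-lead block, combined with a
glucose-trend block.  Each block is arithmetic over only its own
variable set plus the protected functions and decimal constants, so
every evolved model stays a short, readable formula.

Protected functions (total on the reals, so expression evaluation can
never raise):

    plog(x)   = log(1 + |x|)
    psqrt(x)  = sqrt(|x|)
    aq(x, y)  = x / sqrt(1 + y^2)      (analytic quotient)
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

_NT_RE = re.compile(r"<[^<>\s]+>")


@dataclass(frozen=True)
class _NT:
    """Marker wrapper distinguishing nonterminal symbols from literals."""
    name: str


class Grammar:
    """Parsed BNF grammar with ordered production lists.

    Productions are tuples of symbols: ``_NT`` instances for
    nonterminals, plain strings for terminal text.
    """

    def __init__(self, rules: dict[str, list[tuple]], start: str):
        self.rules = rules
        self.start = start
        self._check()
        self.min_depth = self._min_depths()

    def _check(self) -> None:
        if self.start not in self.rules:
            raise ValueError(f"start symbol <{self.start}> has no rule")
        for nt, prods in self.rules.items():
            if not prods:
                raise ValueError(f"nonterminal <{nt}> has an empty production list")
            for prod in prods:
                for sym in prod:
                    if isinstance(sym, _NT) and sym.name not in self.rules:
                        raise ValueError(
                            f"production of <{nt}> references undefined <{sym.name}>")

    def _min_depths(self) -> dict[str, int]:
        """Smallest derivation-tree depth per nonterminal (fixpoint)."""
        depth = {nt: np.inf for nt in self.rules}
        changed = True
        while changed:
            changed = False
            for nt, prods in self.rules.items():
                best = depth[nt]
                for prod in prods:
                    d = 1 + max(
                        [depth[s.name] for s in prod if isinstance(s, _NT)],
                        default=0,
                    )
                    best = min(best, d)
                if best < depth[nt]:
                    depth[nt] = best
                    changed = True
        bad = [nt for nt, d in depth.items() if not np.isfinite(d)]
        if bad:
            raise ValueError(f"nonterminals can never terminate: {bad}")
        return {nt: int(d) for nt, d in depth.items()}

    def production_min_depth(self, prod: tuple) -> int:
        return 1 + max([self.min_depth[s.name] for s in prod if isinstance(s, _NT)],
                       default=0)


def parse_grammar(text: str) -> Grammar:
    """Parse pipe-separated BNF (PonyGE2-style dialect).

    Lines look like ``<expr> ::= <expr>+<expr> | x | y``; a rule may
    continue on following lines that start with ``|``.  Everything that
    is not an ``<angle-bracketed>`` token is literal terminal text
    (surrounding whitespace trimmed).  The first rule's left-hand side is
    the start symbol.
    """
    rules: dict[str, list[tuple]] = {}
    start = None
    current = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "::=" in line:
            lhs, rhs = line.split("::=", 1)
            m = _NT_RE.fullmatch(lhs.strip())
            if not m:
                raise ValueError(f"bad rule head {lhs.strip()!r}")
            current = lhs.strip()[1:-1]
            if start is None:
                start = current
            rules.setdefault(current, [])
        else:
            if current is None:
                raise ValueError(f"production continuation before any rule: {line!r}")
            rhs = line
        for alt in _split_alternatives(rhs):
            rules[current].append(_tokenize(alt))
        rhs = ""  # consumed
    if start is None:
        raise ValueError("no rules found")
    return Grammar(rules, start)


def _split_alternatives(rhs: str) -> list[str]:
    alts = [a.strip() for a in rhs.split("|")]
    return [a for a in alts if a != ""]


def _tokenize(alt: str) -> tuple:
    symbols: list = []
    pos = 0
    for m in _NT_RE.finditer(alt):
        if m.start() > pos:
            lit = alt[pos:m.start()].strip()
            if lit:
                symbols.append(lit)
        symbols.append(_NT(m.group()[1:-1]))
        pos = m.end()
    tail = alt[pos:].strip()
    if tail:
        symbols.append(tail)
    if not symbols:
        raise ValueError(f"empty production alternative in {alt!r}")
    return tuple(symbols)


def map_genome(genome, grammar: Grammar, max_wraps: int = 2,
               max_depth: int = 17) -> tuple[str | None, int]:
    """Map a codon string to a phenotype by leftmost derivation.

    Returns ``(phenotype, used_codons)``; phenotype is ``None`` when the
    derivation fails to terminate within ``max_wraps`` passes over the
    genome or exceeds ``max_depth``.  ``used_codons`` never exceeds the
    genome length (a wrapped read reuses codons already counted).
    """
    genome = list(genome)
    if not genome:
        raise ValueError("empty genome")
    n = len(genome)
    limit = n * (max_wraps + 1)
    consumed = 0
    out: list[str] = []
    stack: list[tuple] = [(_NT(grammar.start), 0)]   # (symbol, depth), LIFO
    while stack:
        sym, depth = stack.pop()
        if not isinstance(sym, _NT):
            out.append(sym)
            continue
        if depth >= max_depth:
            return None, min(consumed, n)
        prods = grammar.rules[sym.name]
        if consumed >= limit:
            return None, n
        codon = genome[consumed % n]
        consumed += 1
        prod = prods[codon % len(prods)]
        for s in reversed(prod):
            stack.append((s, depth + 1) if isinstance(s, _NT) else (s, depth))
    return "".join(out), min(consumed, n)


def random_genome(grammar: Grammar, rng: np.random.Generator,
                  codon_size: int = 100_000,
                  max_init_depth: int = 10) -> list[int]:
    """Grow a random valid derivation and encode it as codons.

    Position-independent grow initialisation: a per-individual depth
    budget is drawn in [min feasible, max_init_depth]; at every expansion
    a production is chosen uniformly among those whose minimum completion
    depth fits the remaining budget, and a codon consistent with that
    choice (``codon mod m == choice``) is drawn uniformly from its
    residue class.  Guarantees a valid, depth-bounded individual.
    """
    start_min = grammar.min_depth[grammar.start]
    if max_init_depth < start_min:
        raise ValueError(
            f"max_init_depth={max_init_depth} below grammar minimum {start_min}")
    budget = int(rng.integers(start_min, max_init_depth + 1))
    codons: list[int] = []
    stack = [(_NT(grammar.start), 0)]
    while stack:
        sym, depth = stack.pop()
        if not isinstance(sym, _NT):
            continue
        prods = grammar.rules[sym.name]
        allowed = [i for i, p in enumerate(prods)
                   if depth + grammar.production_min_depth(p) <= budget]
        if not allowed:   # over budget: fall back to the shallowest production
            dmin = min(grammar.production_min_depth(p) for p in prods)
            allowed = [i for i, p in enumerate(prods)
                       if grammar.production_min_depth(p) == dmin]
        choice = int(allowed[rng.integers(0, len(allowed))])
        m = len(prods)
        q_max = (codon_size - 1 - choice) // m
        codons.append(choice + m * int(rng.integers(0, q_max + 1)))
        for s in reversed(prods[choice]):
            stack.append((s, depth + 1) if isinstance(s, _NT) else (s, depth))
    return codons


# ---------------------------------------------------------------------------
# Protected functions
# ---------------------------------------------------------------------------

def plog(x):
    """log(1 + |x|): protected logarithm, total on the reals."""
    return np.log1p(np.abs(x))


def psqrt(x):
    """sqrt(|x|): protected square root."""
    return np.sqrt(np.abs(x))


def aq(x, y):
    """x / sqrt(1 + y^2): protected analytic quotient (aq(x, 0) == x)."""
    return x / np.sqrt(1.0 + np.square(y))


EVAL_FUNCS = {"plog": plog, "psqrt": psqrt, "aq": aq}


# ---------------------------------------------------------------------------
# The glucose forecasting grammar
# ---------------------------------------------------------------------------

def _block(name: str, var: str) -> str:
    e = f"<{name}>"
    return (f"{e} ::= ({e}<aop>{e}) | plog({e}) | psqrt({e}) | aq({e},{e})"
            f" | <{var}> | <num>")


def glucose_grammar_text(k: int = 12, h: int = 6) -> str:
    """BNF source of the four-block forecasting grammar for given k, h."""
    gvars = " | ".join(f"g{j}" for j in range(k + 1))
    ivars = " | ".join(f"i{j}" for j in range(h + 1))
    cvars = " | ".join(f"c{j}" for j in range(h + 1))
    dvars = " | ".join(f"dg{j}" for j in range(1, k + 1))
    return "\n".join([
        "<expr> ::= (<gexpr>-<iexpr>+<cexpr>)<op><dgexpr>",
        "<op> ::= + | - | *",
        _block("gexpr", "gvar"),
        _block("iexpr", "ivar"),
        _block("cexpr", "cvar"),
        _block("dgexpr", "dgvar"),
        "<aop> ::= + | - | *",
        f"<gvar> ::= {gvars}",
        f"<ivar> ::= {ivars}",
        f"<cvar> ::= {cvars}",
        f"<dgvar> ::= {dvars}",
        "<num> ::= <digit> | <digit>.<digit>",
        "<digit> ::= 0 | 1 | 2 | 3 | 4 | 5 | 6 | 7 | 8 | 9",
    ])


def glucose_grammar(k: int = 12, h: int = 6) -> Grammar:
    """Parsed default forecasting grammar (k past glucose, h future leads)."""
    return parse_grammar(glucose_grammar_text(k, h))
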