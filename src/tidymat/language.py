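"""Tokenizer, parser and printer for the expression / pipeline DSL.

Grammar (infix, R-flavoured)::

    pipeline  := verb_call ("|>" verb_call)*
    verb_call := VERB "(" [item ("," item)*] ")"
    item      := ("rows" | "cols") "(" item ("," item)* ")"
               | [IDENT "="] expr
    expr      := the usual arithmetic / comparison / boolean operators
                 with R precedence, function calls over the registered
                 whitelist, pronouns ".assays$x" / ".rows$x" / ".cols$x"
                 and their "_asis" variants, numeric and double-quoted
                 string literals, TRUE / FALSE / NA, and parentheses.

Strings are double-quoted with backslash escapes; identifiers are word
characters; ``$`` may only follow a pronoun.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Any

import numpy as np

from .core_model import Context, TidymatError
from .masks import CallExpr, Expression, Lit, Pronoun, Sym

__all__ = [
    "ParseError",
    "RawItem",
    "parse_expr",
    "parse_items",
    "parse_calls",
    "render_expr",
    "render_items",
    "render_calls",
    "VERBS",
]

VERBS = {
    "mutate", "filter", "select", "arrange",
    "group_by", "ungroup", "summarize", "summarise", "pull",
}


class ParseError(TidymatError):
    def __init__(self, message: str, line: int, col: int):
        super().__init__(f"{message} (line {line}, column {col})")
        self.line = line
        self.col = col


@dataclasses.dataclass(frozen=True)
class RawItem:
    """One parsed verb argument before verb-specific validation."""

    context: Context
    name: str | None
    expr: Expression


_TOKEN_RE = re.compile(
    r"""
    (?P<WS>\s+)
  | (?P<PRONOUN>\.(?:assays|rows|cols)(?:_asis)?\b)
  | (?P<NUMBER>(?:\d+\.\d*|\.\d+|\d+)(?:[eE][+-]?\d+)?)
  | (?P<IDENT>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<STRING>"(?:\\.|[^"\\])*")
  | (?P<OP>\|>|==|!=|<=|>=|[-+*/^<>&|!()=,$])
    """,
    re.VERBOSE,
)


@dataclasses.dataclass(frozen=True)
class _Token:
    kind: str
    text: str
    line: int
    col: int


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    pos = 0
    line, col = 1, 1
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise ParseError(f"unexpected character {text[pos]!r}", line, col)
        kind = m.lastgroup or ""
        chunk = m.group()
        if kind != "WS":
            tokens.append(_Token(kind, chunk, line, col))
        nl = chunk.count("\n")
        if nl:
            line += nl
            col = len(chunk) - chunk.rfind("\n")
        else:
            col += len(chunk)
        pos = m.end()
    tokens.append(_Token("EOF", "", line, col))
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.tokens = _tokenize(text)
        self.i = 0

    # --- token plumbing ---------------------------------------------------
    @property
    def cur(self) -> _Token:
        return self.tokens[self.i]

    def _advance(self) -> _Token:
        tok = self.cur
        self.i += 1
        return tok

    def _fail(self, message: str) -> "ParseError":
        tok = self.cur
        shown = tok.text or "end of input"
        return ParseError(f"{message}, found {shown!r}", tok.line, tok.col)

    def _expect(self, text: str) -> _Token:
        if self.cur.text != text:
            raise self._fail(f"expected {text!r}")
        return self._advance()

    def _at(self, text: str) -> bool:
        return self.cur.text == text

    # --- expression grammar (precedence climbing) ------------------------
    def expr(self) -> Expression:
        return self._or()

    def _or(self) -> Expression:
        node = self._and()
        while self._at("|"):
            self._advance()
            node = CallExpr("|", (node, self._and()))
        return node

    def _and(self) -> Expression:
        node = self._not()
        while self._at("&"):
            self._advance()
            node = CallExpr("&", (node, self._not()))
        return node

    def _not(self) -> Expression:
        if self._at("!"):
            self._advance()
            return CallExpr("!", (self._not(),))
        return self._cmp()

    def _cmp(self) -> Expression:
        node = self._add()
        if self.cur.text in ("==", "!=", "<", "<=", ">", ">="):
            op = self._advance().text
            node = CallExpr(op, (node, self._add()))
        return node

    def _add(self) -> Expression:
        node = self._mul()
        while self.cur.text in ("+", "-"):
            op = self._advance().text
            node = CallExpr(op, (node, self._mul()))
        return node

    def _mul(self) -> Expression:
        node = self._unary()
        while self.cur.text in ("*", "/"):
            op = self._advance().text
            node = CallExpr(op, (node, self._unary()))
        return node

    def _unary(self) -> Expression:
        if self.cur.text in ("-", "+"):
            op = self._advance().text
            inner = self._unary()
            if op == "-" and isinstance(inner, Lit) and isinstance(inner.value, (int, float)):
                return Lit(-inner.value)
            if op == "+":
                return inner
            return CallExpr(op, (inner,))
        return self._pow()

    def _pow(self) -> Expression:
        node = self._atom()
        if self._at("^"):  # right-associative
            self._advance()
            node = CallExpr("^", (node, self._unary()))
        return node

    def _atom(self) -> Expression:
        tok = self.cur
        if tok.kind == "NUMBER":
            self._advance()
            text = tok.text
            if re.fullmatch(r"\d+", text):
                return Lit(int(text))
            return Lit(float(text))
        if tok.kind == "STRING":
            self._advance()
            body = tok.text[1:-1]
            return Lit(re.sub(r"\\(.)", r"\1", body))
        if tok.kind == "PRONOUN":
            self._advance()
            base = tok.text.lstrip(".")
            variant = "asis" if base.endswith("_asis") else "reshaped"
            target = Context(base.removesuffix("_asis"))
            self._expect("$")
            name_tok = self.cur
            if name_tok.kind != "IDENT":
                raise self._fail("expected a name after '$'")
            self._advance()
            return Pronoun(target, variant, name_tok.text)
        if tok.kind == "IDENT":
            self._advance()
            if tok.text in ("TRUE", "FALSE"):
                return Lit(tok.text == "TRUE")
            if tok.text == "NA":
                return Lit(np.nan)
            if self._at("("):
                self._advance()
                args: list[Expression] = []
                if not self._at(")"):
                    args.append(self.expr())
                    while self._at(","):
                        self._advance()
                        args.append(self.expr())
                self._expect(")")
                return CallExpr(tok.text, tuple(args))
            return Sym(tok.text)
        if self._at("("):
            self._advance()
            node = self.expr()
            self._expect(")")
            return node
        raise self._fail("expected an expression")

    # --- item grammar -----------------------------------------------------
    def item(self, context: Context = Context.ASSAYS) -> list[RawItem]:
        tok = self.cur
        if tok.kind == "IDENT" and tok.text in ("rows", "cols") and self.tokens[self.i + 1].text == "(":
            if context is not Context.ASSAYS:
                raise self._fail("sentinels cannot be nested")
            target = Context.ROWS if tok.text == "rows" else Context.COLS
            self._advance()
            self._advance()  # "("
            items: list[RawItem] = []
            items.extend(self.item(target))
            while self._at(","):
                self._advance()
                items.extend(self.item(target))
            self._expect(")")
            return items
        name = None
        if tok.kind == "IDENT" and self.tokens[self.i + 1].text == "=":
            name = tok.text
            self._advance()
            self._advance()
        return [RawItem(context, name, self.expr())]

    def items(self) -> list[RawItem]:
        out: list[RawItem] = []
        if self.cur.kind == "EOF" or self._at(")"):
            return out
        out.extend(self.item())
        while self._at(","):
            self._advance()
            out.extend(self.item())
        return out

    # --- verb call / pipeline grammar ------------------------------------
    def verb_call(self) -> tuple[str, list[RawItem]]:
        tok = self.cur
        if tok.kind != "IDENT" or tok.text not in VERBS:
            raise self._fail("expected a verb name")
        verb = self._advance().text
        if verb == "summarise":
            verb = "summarize"
        self._expect("(")
        items = self.items()
        self._expect(")")
        return verb, items

    def pipeline(self) -> list[tuple[str, list[RawItem]]]:
        calls = [self.verb_call()]
        while self._at("|>"):
            self._advance()
            calls.append(self.verb_call())
        return calls

    def finish(self) -> None:
        if self.cur.kind != "EOF":
            raise self._fail("unexpected trailing input")


def parse_expr(text: str) -> Expression:
    p = _Parser(text)
    node = p.expr()
    p.finish()
    return node


def parse_items(text: str) -> list[RawItem]:
    """Parse one verb-argument string into items (sentinels unwrapped)."""
    p = _Parser(text)
    out = p.items()
    p.finish()
    return out


def parse_calls(text: str) -> list[tuple[str, list[RawItem]]]:
    p = _Parser(text)
    calls = p.pipeline()
    p.finish()
    return calls


# --------------------------------------------------------------------------
# Printer (inverse of the parser, up to whitespace and parentheses)
# --------------------------------------------------------------------------

_BINARY_OPS = {"+", "-", "*", "/", "^", "==", "!=", "<", "<=", ">", ">=", "&", "|"}


def render_expr(expr: Expression) -> str:
    if isinstance(expr, Lit):
        v = expr.value
        if isinstance(v, bool):
            return "TRUE" if v else "FALSE"
        if isinstance(v, float) and np.isnan(v):
            return "NA"
        if isinstance(v, str):
            return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
        return repr(v)
    if isinstance(expr, Sym):
        return expr.name
    if isinstance(expr, Pronoun):
        suffix = "_asis" if expr.variant == "asis" else ""
        return f".{expr.target.value}{suffix}${expr.name}"
    if isinstance(expr, CallExpr):
        if expr.fn in _BINARY_OPS and len(expr.args) == 2:
            a, b = expr.args
            return f"({render_expr(a)} {expr.fn} {render_expr(b)})"
        if expr.fn in ("-", "+", "!") and len(expr.args) == 1:
            return f"({expr.fn}{render_expr(expr.args[0])})"
        return f"{expr.fn}({', '.join(render_expr(a) for a in expr.args)})"
    raise TypeError(f"not an expression node: {expr!r}")


def render_items(items: list[RawItem]) -> str:
    chunks: list[str] = []
    for it in items:
        body = render_expr(it.expr) if it.name is None else f"{it.name} = {render_expr(it.expr)}"
        if it.context is Context.ASSAYS:
            chunks.append(body)
        else:
            chunks.append(f"{it.context.value}({body})")
    return ", ".join(chunks)


def render_calls(calls: list[tuple[str, list[Any]]]) -> str:
    parts = []
    for verb, items in calls:
        parts.append(f"{verb}({render_items(list(items))})")
    return " |> ".join(parts)
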