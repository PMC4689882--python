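"""Constituent-parse-tree features: heights and part-of-speech root paths.

For each of P1, P2 and the keyword the feature set records the labels on the
path from (just below) the root down to the token's preterminal, plus the
length of that path ("height"). With the bracketed tree for
"P1 is driven by P2"::

    (S (NP (NN P1)) (VP (VBZ is) (VP (VBN driven) (PP (IN by) (NP (NN P2))))))

the POS paths are "NP,NN" / "VP,VP,PP,NP,NN" / "VP,VP,VBN" and the heights
2 / 5 / 3: the root label is excluded, the preterminal included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .corpus_io import Instance, Token

HEIGHT_SENTINEL = -1
PATH_SENTINEL = "none"


@dataclass
class TreeNode:
    label: str
    children: list["TreeNode"] = field(default_factory=list)
    word: Optional[str] = None  # set on leaves only

    @property
    def is_leaf(self) -> bool:
        return self.word is not None


@dataclass
class ParseTree:
    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def root_path(self, leaf_index: int) -> list[str]:
        """Labels from the child of the root down to the leaf's preterminal."""
        path: list[str] = []

        def walk(node: TreeNode, count: list[int]) -> bool:
            if node.is_leaf:
                if count[0] == leaf_index:
                    path.append(node.label)  # the preterminal POS tag
                    return True
                count[0] += 1
                return False
            for c in node.children:
                if walk(c, count):
                    path.append(node.label)
                    return True
            return False

        if not walk(self.root, [0]):
            raise IndexError(f"no leaf with index {leaf_index}")
        labels = list(reversed(path))
        return labels[1:]  # drop the root label; preterminal stays


def parse_bracketed(text: str) -> ParseTree:
    """Parse one Penn-Treebank-style bracketed tree string."""
    pos = 0
    n = len(text)

    def skip_ws() -> None:
        nonlocal pos
        while pos < n and text[pos].isspace():
            pos += 1

    def read_atom() -> str:
        nonlocal pos
        start = pos
        while pos < n and not text[pos].isspace() and text[pos] not in "()":
            pos += 1
        if start == pos:
            raise ValueError(f"expected a label at position {start}")
        return text[start:pos]

    def read_node() -> TreeNode:
        nonlocal pos
        skip_ws()
        if pos >= n or text[pos] != "(":
            raise ValueError(f"expected '(' at position {pos}")
        pos += 1
        skip_ws()
        label = read_atom()
        node = TreeNode(label=label)
        while True:
            skip_ws()
            if pos >= n:
                raise ValueError("unbalanced brackets: unexpected end of input")
            if text[pos] == ")":
                pos += 1
                return node
            if text[pos] == "(":
                node.children.append(read_node())
            else:
                word = read_atom()
                if node.children or node.word is not None:
                    raise ValueError(
                        f"mixed leaf/children under {label!r} at position {pos}")
                node.word = word

    root = read_node()
    skip_ws()
    if pos != n:
        raise ValueError(f"trailing input after tree at position {pos}")
    return ParseTree(root=root)


def to_bracketed(tree: ParseTree) -> str:
    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return f"({node.label} {node.word})"
        return f"({node.label} " + " ".join(fmt(c) for c in node.children) + ")"

    return fmt(tree.root)


def root_path(tree: ParseTree, token: Token) -> list[str]:
    if not token.is_word or token.index is None:
        raise ValueError(f"token {token.surface!r} is not a word token")
    return tree.root_path(token.index)


def height_features(tree: Optional[ParseTree], instance: Instance,
                    keyword: Optional[Token]) -> tuple[int, int, int]:
    """(height_P1, height_P2, height_K); sentinel -1 where undefined."""
    paths = pos_paths(tree, instance, keyword)
    return tuple(HEIGHT_SENTINEL if p == PATH_SENTINEL else len(p.split(","))
                 for p in paths)  # type: ignore[return-value]


def pos_paths(tree: Optional[ParseTree], instance: Instance,
              keyword: Optional[Token]) -> tuple[str, str, str]:
    """Comma-joined POS root paths for (P1, P2, K); "none" where undefined."""
    if tree is None:
        return (PATH_SENTINEL, PATH_SENTINEL, PATH_SENTINEL)
    n_leaves = len(tree.leaves())

    def path_at(index: Optional[int]) -> str:
        if index is None or not (0 <= index < n_leaves):
            return PATH_SENTINEL
        return ",".join(tree.root_path(index))

    p1 = path_at(instance.p1.token_span[1] - 1)
    p2 = path_at(instance.p2.token_span[1] - 1)
    k = path_at(keyword.index) if keyword is not None else PATH_SENTINEL
    return (p1, p2, k)
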