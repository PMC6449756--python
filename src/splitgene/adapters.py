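"""Adapters for external aligners and tree builders (disabled by default).

An adapter wraps a shell command template with ``{in}`` and ``{out}``
placeholders and exposes the same contract as the built-in engine: an
aligner maps sequences to an :class:`~splitgene.seqdata.Alignment` whose
ungapped rows equal its inputs; a tree builder maps an alignment to a
:class:`~splitgene.trees.PhyloTree` over the same leaf set, with supports
normalized to [0, 1].  A missing executable is a configuration error raised
when the adapter is constructed, not mid-run.
"""

from __future__ import annotations

import shlex
import shutil
import subprocess
import tempfile
from pathlib import Path
from typing import Sequence

from .seqdata import Alignment, ProteinSequence, read_alignment, write_fasta
from .trees import PhyloTree, read_newick


class AdapterError(RuntimeError):
    pass


class ExternalTool:
    """A configured external command with validated outputs."""

    def __init__(self, kind: str, template: str):
        if kind not in ("aligner", "treebuilder"):
            raise ValueError(f"unknown adapter kind {kind!r}")
        self.kind = kind
        self.template = template
        exe = shlex.split(template)[0]
        if shutil.which(exe) is None:
            raise AdapterError(
                f"{kind} adapter: executable {exe!r} not found on PATH")

    def _run(self, infile: Path, outfile: Path) -> None:
        cmd = self.template.replace("{in}", str(infile)).replace(
            "{out}", str(outfile))
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        if proc.returncode != 0:
            raise AdapterError(
                f"{self.kind} command failed ({proc.returncode}): "
                f"{cmd}\n{proc.stderr.strip()}")

    def align(self, seqs: Sequence[ProteinSequence]) -> Alignment:
        if self.kind != "aligner":
            raise AdapterError("not an aligner adapter")
        with tempfile.TemporaryDirectory() as tmp:
            inf = Path(tmp) / "in.fa"
            outf = Path(tmp) / "out.fa"
            write_fasta(seqs, inf)
            self._run(inf, outf)
            aln = read_alignment(outf)
        ids = {s.id for s in seqs}
        if set(aln.ids()) != ids:
            raise AdapterError("aligner changed the sequence set")
        for s in seqs:
            if aln.ungapped(s.id) != s.residues:
                raise AdapterError(f"aligner altered sequence {s.id}")
        return aln

    def build_tree(self, msa: Alignment) -> PhyloTree:
        if self.kind != "treebuilder":
            raise AdapterError("not a treebuilder adapter")
        with tempfile.TemporaryDirectory() as tmp:
            inf = Path(tmp) / "in.fa"
            outf = Path(tmp) / "out.nwk"
            from .seqdata import write_alignment
            write_alignment(msa, inf)
            self._run(inf, outf)
            tree = read_newick(outf)
        if set(tree.leaf_names()) != set(msa.ids()):
            raise AdapterError("tree builder changed the leaf set")
        for node in tree.postorder():
            if node.support is not None and not (0.0 <= node.support <= 1.0):
                raise AdapterError(f"support {node.support} outside [0,1]")
        return tree


def mafft_adapter(extra_args: str = "--auto --quiet") -> ExternalTool:
    return ExternalTool("aligner", f"mafft {extra_args} {{in}} > {{out}}")


def fasttree_adapter(extra_args: str = "-quiet") -> ExternalTool:
    return ExternalTool("treebuilder", f"fasttree {extra_args} {{in}} > {{out}}")
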