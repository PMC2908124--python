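"""File I/O: FASTA alignments, Newick trees, TSV tables and JSON logs."""

from __future__ import annotations

import json
import sys
from pathlib import Path

from Bio import SeqIO

from .benchmark import AlignmentBenchmark, EnsembleResult, bic, summarize
from .gencode import GeneticCode, universal_code
from .inference import CodonAlignment, FitResult, PhyloTree


def read_codon_fasta(path: str | Path, code: GeneticCode | None = None) -> CodonAlignment:
    """Read an in-frame nucleotide FASTA alignment as codon states.

    Enforces equal sequence lengths and a length divisible by 3; any
    codon containing a gap or ambiguity character becomes missing data,
    and stop codons are rejected with the offending sequence and site.
    """
    code = code or universal_code()
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return CodonAlignment.from_sequences(records, code)


def write_fasta(aln: CodonAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in aln.sequences():
            fh.write(f">{name}\n{seq}\n")


def read_newick(
    path: str | Path, require_branch_lengths: bool = True
) -> PhyloTree:
    """Read a Newick tree file.

    By default every edge must carry a branch length; pass
    ``require_branch_lengths=False`` to accept a bare topology whose
    lengths will be initialized by the fitter.
    """
    text = Path(path).read_text()
    tree = PhyloTree.from_newick(text)
    if require_branch_lengths and not tree.has_branch_lengths():
        raise ValueError(
            f"tree in {path} is missing branch lengths; pass "
            f"require_branch_lengths=False (CLI: --init-branch-lengths) to "
            f"initialize them from the data"
        )
    return tree


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def check_taxa(tree: PhyloTree, aln: CodonAlignment) -> None:
    """Raise if tree and alignment do not name the same taxa."""
    only_tree = sorted(set(tree.taxa) - set(aln.taxa))
    only_aln = sorted(set(aln.taxa) - set(tree.taxa))
    if only_tree or only_aln:
        raise ValueError(
            f"taxa mismatch: in tree only {only_tree}, in alignment only {only_aln}"
        )


def write_fit_json(result: FitResult, path: str | Path) -> None:
    Path(path).write_text(result.to_json() + "\n")


def _replicate_log(ens: EnsembleResult, n_sites: int) -> list[dict]:
    rows = []
    for seed, f, c in zip(ens.seeds, ens.fits, ens.comparisons):
        rows.append(
            {
                "seed": seed,
                "log_likelihood": f.log_likelihood,
                "converged": f.converged,
                "n_free_parameters": f.n_free_parameters,
                "df": c.df if c else None,
                "lr_statistic": c.lr_statistic if c else None,
                "p_value": c.p_value if c else None,
                "significant_raw": c.significant_raw if c else None,
                "significant_bonferroni": c.significant_bonferroni if c else None,
                "bic": bic(f, n_sites) if f.converged else None,
            }
        )
    return rows


def write_outputs(records: list[AlignmentBenchmark], out_dir: str | Path) -> dict:
    """Write table1.tsv / table2.tsv and a JSON log of every replicate.

    Returns the paths written, for logging.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sig, bic_table = summarize(records)
    t1 = out / "table1.tsv"
    t2 = out / "table2.tsv"
    sig.to_csv(t1, sep="\t", index=False)
    bic_table.to_csv(t2, sep="\t", index=False)

    log = {
        "python": sys.version.split()[0],
        "alignments": {
            r.label: {
                "n_taxa": r.n_taxa,
                "n_sites": r.n_sites,
                "sr_bic": {
                    k: e.sr_bic for k, e in r.ensembles.items()
                },
                "ensembles": {
                    k: {
                        "K": e.K,
                        "alpha": e.alpha,
                        "n_replicates": e.n_replicates,
                        "n_significant_raw": e.n_significant_raw,
                        "n_significant_bonferroni": e.n_significant_bonferroni,
                        "n_nonconverged": e.n_nonconverged,
                        "mean_bic": e.mean_bic,
                        "replicates": _replicate_log(e, r.n_sites),
                    }
                    for k, e in r.ensembles.items()
                },
            }
            for r in records
        },
    }
    lp = out / "replicates.json"
    lp.write_text(json.dumps(log, indent=1) + "\n")
    return {"table1": str(t1), "table2": str(t2), "log": str(lp)}
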