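"""Independent reference implementations used as test oracles.

Deliberately naive: plain loops and direct formula evaluation, sharing no
code paths with the package implementations they check.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_contacts(model, conf, params):
    """All-pairs confident-contact filter.

    Loops over every inter-chain residue pair, takes the minimum pairwise
    atom distance by explicit broadcasting, and applies the three strict
    threshold rules.  Returns a set of canonical contact keys.
    """
    found = set()
    chains = model.chains
    for i in range(len(chains)):
        for j in range(i + 1, len(chains)):
            for ra in chains[i].residues:
                ca = ra.coords()
                for rb in chains[j].residues:
                    cb = rb.coords()
                    d = np.sqrt(
                        ((ca[:, None, :] - cb[None, :, :]) ** 2).sum(axis=2)
                    ).min()
                    if not d < params.distance_cutoff:
                        continue
                    ida = (chains[i].chain_id, ra.resnum)
                    idb = (chains[j].chain_id, rb.resnum)
                    pl_a = conf.plddt_of(*ida)
                    pl_b = conf.plddt_of(*idb)
                    if not (pl_a > params.plddt_min and pl_b > params.plddt_min):
                        continue
                    pae_ab = conf.pae_of(ida, idb)
                    pae_ba = conf.pae_of(idb, ida)
                    if params.pae_combine == "min":
                        combined = min(pae_ab, pae_ba)
                    elif params.pae_combine == "mean":
                        combined = (pae_ab + pae_ba) / 2.0
                    else:
                        combined = max(pae_ab, pae_ba)
                    if not combined < params.pae_max:
                        continue
                    pair = tuple(sorted((ida, idb)))
                    found.add(pair)
    return found


def avg_models_enumeration(contact_key_sets, n_models):
    """Direct enumeration of the ensemble-agreement score."""
    union = set().union(*contact_key_sets) if contact_key_sets else set()
    if not union:
        return 0.0
    total = 0
    for key in union:
        total += sum(1 for s in contact_key_sets if key in s)
    return total / (len(union) * n_models)


def pdockq_reference(mean_interface_plddt, n_contacts):
    """Direct evaluation of the published pDockQ sigmoid.

    pDockQ = 0.724 / (1 + exp(-0.052 (x - 152.611))) + 0.018 with
    x = <pLDDT over interface residues> * ln(contact count); defined as
    0 for contact-free interfaces.
    """
    if n_contacts == 0:
        return 0.0
    x = mean_interface_plddt * math.log(n_contacts)
    return 0.724 / (1.0 + math.exp(-0.052 * (x - 152.611))) + 0.018


def pdockq_interface_reference(model, conf):
    """Naive pDockQ contact census: CB (CA for Gly) pairs within 8 Å."""
    def bead(res):
        a = res.atom("CB")
        if a is None or res.resname == "GLY":
            a = res.atom("CA")
        return a

    chains = model.chains
    n_contacts = 0
    interface = set()
    for i in range(len(chains)):
        for j in range(i + 1, len(chains)):
            for ra in chains[i].residues:
                aa = bead(ra)
                if aa is None:
                    continue
                for rb in chains[j].residues:
                    ab = bead(rb)
                    if ab is None:
                        continue
                    if np.linalg.norm(aa.xyz - ab.xyz) <= 8.0:
                        n_contacts += 1
                        interface.add((chains[i].chain_id, ra.resnum))
                        interface.add((chains[j].chain_id, rb.resnum))
    if n_contacts == 0:
        return 0.0, 0
    mean_plddt = float(np.mean([conf.plddt_of(*r) for r in interface]))
    return pdockq_reference(mean_plddt, n_contacts), n_contacts


def naive_clash_pairs(composite, rule, excluded_chain_pairs):
    """O(n^2) clash census over all inter-component heavy-atom pairs."""
    comps = composite.components
    flat = []
    for comp in comps:
        for ch in comp.model.chains:
            for r in ch.residues:
                for a in r.atoms:
                    flat.append((comp.component_id, ch.chain_id, r.resnum, a.name,
                                 a.element, a.xyz))
    out = set()
    for x in range(len(flat)):
        for y in range(x + 1, len(flat)):
            ca, cb = flat[x], flat[y]
            if ca[0] == cb[0]:
                continue
            if frozenset({(ca[0], ca[1]), (cb[0], cb[1])}) in excluded_chain_pairs:
                continue
            d = float(np.linalg.norm(ca[5] - cb[5]))
            if d < rule.threshold(ca[4], cb[4]):
                out.add(((ca[0], ca[1], ca[2], ca[3]), (cb[0], cb[1], cb[2], cb[3])))
    return out
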