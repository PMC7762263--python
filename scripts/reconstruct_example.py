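"""Reconstruct the 16-node worked-example graph from its printed constraints.

Known constraints:
- degrees (1..16): 5 4 4 5 3 4 4 2 5 4 5 4 4 2 2 3  (30 edges)
- k-core:          3 3 3 3 3 3 3 2 3 3 3 3 2 2 2 2
- N(1) = {2,3,4,5,11}  (candidate SL row: 2,3,4,5,11 at distance 1)
- candidate set of node 1 = {2,3,4,5,6,9,10,11,12}
- Attr(1,j) 2dp: 2:0.64 3:0.64 4:0.8 5:0.36 6:0.08 9:0.1 10:0.08 11:0.4, 12 in {0.04,0.08}
- pair vector: 4 1 1 1 1 9 9 9 6 9 10 11 16 13 13 13 (lowest-label ties)
- final communities {1..5},{6..12},{13..16}
"""
import itertools, sys
from iacd.graph_io import Network, Partition
from iacd import core

DEG = {str(i): d for i, d in zip(range(1, 17),
      [5, 4, 4, 5, 3, 4, 4, 2, 5, 4, 5, 4, 4, 2, 2, 3])}
KCORE = {str(i): k for i, k in zip(range(1, 17),
        [3, 3, 3, 3, 3, 3, 3, 2, 3, 3, 3, 3, 2, 2, 2, 2])}
EXP_PAIRS = {str(i): str(p) for i, p in zip(range(1, 17),
            [4, 1, 1, 1, 1, 9, 9, 9, 6, 9, 10, 11, 16, 13, 13, 13])}
EXP_ATTR = {"2": 0.64, "3": 0.64, "4": 0.8, "5": 0.36, "6": 0.08,
            "9": 0.1, "10": 0.08, "11": 0.4}
EXP_SL = {"2": 1, "3": 1, "4": 1, "5": 1, "6": 2, "9": 2, "10": 2, "11": 1, "12": 2}
EXP_CAND1 = {"2", "3", "4", "5", "6", "9", "10", "11", "12"}
C1, C2, C3 = ["1", "2", "3", "4", "5"], ["6", "7", "8", "9", "10", "11", "12"], \
             ["13", "14", "15", "16"]
EXP_COMMS = [set(C1), set(C2), set(C3)]


def graphs_with_degrees(nodes, degs):
    """All labeled simple graphs on `nodes` with the given degree dict."""
    nodes = list(nodes)

    def rec(rem, avail_edges):
        if all(r == 0 for r in rem.values()):
            yield []
            return
        # pick node with max remaining degree to branch on
        v = max((n for n in nodes if rem[n] > 0), key=lambda n: rem[n])
        partners = [u for u in nodes if u != v and rem[u] > 0
                    and frozenset((u, v)) in avail_edges]
        if len(partners) < rem[v]:
            return
        for combo in itertools.combinations(partners, rem[v]):
            new_rem = dict(rem)
            new_rem[v] = 0
            ok = True
            for u in combo:
                new_rem[u] -= 1
            new_avail = avail_edges - {frozenset((v, u)) for u in nodes if u != v}
            for tail in rec(new_rem, new_avail):
                yield [frozenset((v, u)) for u in combo] + tail

    all_edges = {frozenset(p) for p in itertools.combinations(nodes, 2)}
    yield from rec(dict(degs), all_edges)


def validate(edges):
    net = Network.from_edges([tuple(sorted(e)) for e in edges], warn=False)
    if {v: net.degree(v) for v in net.nodes} != DEG:
        return False
    if core.kcore_scores(net) != KCORE:
        return False
    if net.neighbors("1") != {"2", "3", "4", "5", "11"}:
        return False
    if core.candidate_set(net, "1") != EXP_CAND1:
        return False
    inf = core.influence_table(net)
    for j, a in EXP_ATTR.items():
        rec = core.attraction(net, inf, "1", j)
        if rec.sl != EXP_SL[j] or round(rec.attr, 2) != a:
            return False
    rec12 = core.attraction(net, inf, "1", "12")
    if rec12.sl != 2 or abs(rec12.attr - 0.06) > 0.02 + 1e-9:
        return False
    pairs = core.build_pair_table(net, inf)
    if pairs.as_dict() != EXP_PAIRS:
        return False
    part = core.detect(net)
    if sorted(part.community_sets(), key=lambda s: min(map(int, s))) != EXP_COMMS:
        return False
    return True


def main():
    solutions = []
    seen = set()
    c2others = ["6", "9", "10", "12"]
    for w in ["2", "3", "4", "5"]:          # the C1 node adjacent to 11
        for u in ["2", "3", "4", "5"]:      # the C1 node adjacent to X
            for X in c2others:              # 4th-column cross target
                for e in C3:                # C3 node with the cross edge
                    for Y in C2:            # its C2 partner
                        cross = [("1", "11"), (w, "11"), (u, X), (e, Y)]
                        # C1 internal: 1-j forced; enumerate edges among 2..5
                        d1 = {}
                        bad = False
                        for j in ["2", "3", "4", "5"]:
                            d = DEG[j] - 1 - (j == w) - (j == u)
                            if d < 0:
                                bad = True
                            d1[j] = d
                        if bad:
                            continue
                        d3 = {j: DEG[j] - (j == e) for j in C3}
                        d2 = {j: DEG[j] - (j == Y) - (j == X) - 2 * (j == "11")
                              for j in C2}
                        if any(v < 0 for v in d2.values()) or sum(d2.values()) % 2:
                            continue
                        if sum(d1.values()) % 2 or sum(d3.values()) % 2:
                            continue
                        for g1 in graphs_with_degrees(["2", "3", "4", "5"], d1):
                            # quick triangle check: T(1,j) = deg within {2..5} + (j==w)
                            tri = {j: sum(1 for ed in g1 if j in ed) + (j == w)
                                   for j in ["2", "3", "4", "5"]}
                            if (tri["2"], tri["3"], tri["4"], tri["5"]) != (3, 3, 3, 2):
                                continue
                            for g3 in graphs_with_degrees(C3, d3):
                                for g2 in graphs_with_degrees(C2, d2):
                                    edges = (
                                        [frozenset(("1", j)) for j in ["2", "3", "4", "5"]]
                                        + [frozenset(c) for c in cross]
                                        + g1 + g2 + g3)
                                    key = frozenset(edges)
                                    if len(key) != 30 or key in seen:
                                        continue
                                    seen.add(key)
                                    if validate(edges):
                                        solutions.append(key)
                                        print("SOLUTION:", sorted(
                                            (tuple(sorted(e, key=int)) for e in key),
                                            key=lambda t: (int(t[0]), int(t[1]))))
    print(f"{len(solutions)} solution(s); {len(seen)} candidate graphs examined")


if __name__ == "__main__":
    main()
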