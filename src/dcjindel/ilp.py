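"""Capping-free integer linear program for the DCJ-indel distance of
natural genomes.

The program searches over consistent decompositions of the augmented MRD —
equivalently, over matchings between the two genomes' markers — and scores
each by the component-census distance formula.  Linear chromosomes are
handled without capping: inert pseudo-cap vertices anchor every telomere,
so the solution space does not blow up with the chromosome count.

Component types are detected through binary *report* variables sitting on
adjacency edges and licensed by a component-labelling scheme:

* ``x`` selects extremity/indel edges (sibling head/tail edges agree);
* ``y``/``z`` propagate the minimum vertex id through each lava-free
  component and mark its minimum vertex, licensing one cycle or
  telomere-to-telomere path report per component;
* ``l`` labels path endpoints by genome (0 for A, 1 for B), pinned
  statically at pseudo-caps and dynamically at lava vertices; a label
  change along a component is only possible at an edge reporting an
  odd path type, which forces odd paths to be reported;
* pseudo-caps whose component contains a lava vertex (``y = 0``) must
  report a pier.

The objective ``n - c + q + s`` mirrors the closed-form distance, with the
integer ``q`` implementing the ceiling of the path-term fraction through
four lower bounds and ``s`` counting circular singletons via per-chromosome
indicator variables.  Report variables may legally over-report only
cost-increasing types, so distances and matchings handed back to callers
are always recomputed from the selected edges, never read off reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .distance import formula_distance, resolved_distance
from .genomes import FamilyAssignment, Genome, ResolvedMatching
from .mrd import ComponentReport, MRDGraph

MATCHING_MODELS = ("maximum", "intermediate", "exemplar")


@dataclass(frozen=True)
class FamilyBounds:
    """Per-family lower/upper bounds on the number of matched pairs."""

    bounds: dict[str, tuple[int, int]]

    def __getitem__(self, fam: str) -> tuple[int, int]:
        return self.bounds[fam]


def family_bounds(fams: FamilyAssignment, model: str = "maximum") -> FamilyBounds:
    """Bounds enforcing a matching model.

    ``maximum`` matches min(|f_A|, |f_B|) pairs per family, ``exemplar``
    exactly one, ``intermediate`` between one and the maximum.  Families
    present in only one genome are never matched.
    """
    if model not in MATCHING_MODELS:
        raise ValueError(f"unknown matching model {model!r}; choose from {MATCHING_MODELS}")
    out = {}
    for f, (in_a, in_b) in fams.families.items():
        lo = min(len(in_a), len(in_b))
        if lo == 0:
            out[f] = (0, 0)
        elif model == "maximum":
            out[f] = (lo, lo)
        elif model == "intermediate":
            out[f] = (1, lo)
        else:
            out[f] = (1, 1)
    return FamilyBounds(out)


# ---------------------------------------------------------------------------
# Abstract model container
# ---------------------------------------------------------------------------

@dataclass
class IlpModel:
    """A mixed-integer program: variables, linear constraints, objective.

    Solver-agnostic; can be handed to :func:`solve` (HiGHS via scipy) or
    serialized to the LP/MPS text dialects for any external MIP solver.
    """

    var_names: list[str] = field(default_factory=list)
    var_index: dict[str, int] = field(default_factory=dict)
    lb: list[float] = field(default_factory=list)
    ub: list[float] = field(default_factory=list)
    integer: list[bool] = field(default_factory=list)
    #: constraints as (name, {var: coeff}, lower, upper)
    constraints: list[tuple[str, dict[str, float], float, float]] = field(
        default_factory=list
    )
    objective: dict[str, float] = field(default_factory=dict)

    def add_var(
        self, name: str, lb: float = 0.0, ub: float = 1.0, integer: bool = True
    ) -> str:
        if name in self.var_index:
            raise ValueError(f"duplicate variable {name}")
        self.var_index[name] = len(self.var_names)
        self.var_names.append(name)
        self.lb.append(lb)
        self.ub.append(ub)
        self.integer.append(integer)
        return name

    def add_constraint(
        self,
        name: str,
        coeffs: dict[str, float],
        lb: float = -math.inf,
        ub: float = math.inf,
    ) -> None:
        self.constraints.append((name, coeffs, lb, ub))

    @property
    def n_vars(self) -> int:
        return len(self.var_names)

    # -- serialization ------------------------------------------------

    def to_lp(self) -> str:
        """CPLEX-style LP text."""

        def term(coef, var, first):
            sign = "-" if coef < 0 else ("" if first else "+")
            mag = abs(coef)
            mag_s = f"{mag:g} " if mag != 1 else ""
            return f"{sign} {mag_s}{var}".strip()

        lines = ["Minimize", " obj: " + " ".join(
            term(c, v, i == 0)
            for i, (v, c) in enumerate(sorted(self.objective.items()))
        )]
        lines.append("Subject To")
        for name, coeffs, lo, hi in self.constraints:
            expr = " ".join(
                term(c, v, i == 0) for i, (v, c) in enumerate(sorted(coeffs.items()))
            )
            if lo == hi:
                lines.append(f" {name}: {expr} = {lo:g}")
            else:
                if hi != math.inf:
                    lines.append(f" {name}_u: {expr} <= {hi:g}")
                if lo != -math.inf:
                    lines.append(f" {name}_l: {expr} >= {lo:g}")
        lines.append("Bounds")
        for i, v in enumerate(self.var_names):
            lines.append(f" {self.lb[i]:g} <= {v} <= {self.ub[i]:g}")
        ints = [v for i, v in enumerate(self.var_names) if self.integer[i]]
        if ints:
            lines.append("Generals")
            lines.append(" " + " ".join(ints))
        lines.append("End")
        return "\n".join(lines) + "\n"

    def to_mps(self) -> str:
        """Free-format MPS text (two-sided rows split into L/G pairs)."""
        rows: list[tuple[str, str]] = []  # (sense, name)
        row_coeffs: list[tuple[str, dict[str, float], float]] = []
        for name, coeffs, lo, hi in self.constraints:
            if lo == hi:
                rows.append(("E", name))
                row_coeffs.append((name, coeffs, lo))
            else:
                if hi != math.inf:
                    rows.append(("L", name + "_u"))
                    row_coeffs.append((name + "_u", coeffs, hi))
                if lo != -math.inf:
                    rows.append(("G", name + "_l"))
                    row_coeffs.append((name + "_l", coeffs, lo))
        lines = ["NAME dcjindel", "ROWS", " N obj"]
        for sense, name in rows:
            lines.append(f" {sense} {name}")
        lines.append("COLUMNS")
        per_col: dict[str, list[tuple[str, float]]] = {v: [] for v in self.var_names}
        for v, c in self.objective.items():
            per_col[v].append(("obj", c))
        for name, coeffs, _ in row_coeffs:
            for v, c in coeffs.items():
                per_col[v].append((name, c))
        for i, v in enumerate(self.var_names):
            if self.integer[i]:
                lines.append(f" MARKER{i} 'MARKER' 'INTORG'")
            for row, c in per_col[v]:
                lines.append(f" {v} {row} {c:g}")
            if self.integer[i]:
                lines.append(f" MARKER{i}X 'MARKER' 'INTEND'")
        lines.append("RHS")
        for name, _, rhs in row_coeffs:
            if rhs != 0:
                lines.append(f" RHS {name} {rhs:g}")
        lines.append("BOUNDS")
        for i, v in enumerate(self.var_names):
            lines.append(f" LO BND {v} {self.lb[i]:g}")
            lines.append(f" UP BND {v} {self.ub[i]:g}")
        lines.append("ENDATA")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class IlpSolution:
    """Solver outcome: status, objective, dual bound and assignment."""

    status: str  # "optimal" or "feasible-with-gap"
    objective: int
    bound: float
    assignment: dict[str, float]

    @property
    def gap(self) -> float:
        if self.objective == 0:
            return 0.0
        return (self.objective - self.bound) / self.objective


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

def _vname(v) -> str:
    """LP-safe vertex name."""
    return f"{v[0]}_{v[1]}" if v[0] == "cap" else f"{v[0]}{v[1]}"


def build_model(m: MRDGraph, bounds: FamilyBounds) -> IlpModel:
    """Encode the capping-free distance program over an augmented MRD."""
    if not m.augmented:
        raise ValueError("build_model requires an augmented MRD")
    ix = m.ix
    big_m = max(ix.values()) if ix else 0
    mod = IlpModel()

    # --- edge selection variables -------------------------------------
    pair_var: dict[tuple[int, int], str] = {}
    ext_at_vertex: dict = {}
    for i, e in enumerate(m.extremity_edges):
        name = mod.add_var(f"x_{e.kind}_{e.pair[0]}_{e.pair[1]}")
        ext_at_vertex.setdefault(e.u, []).append(name)
        ext_at_vertex.setdefault(e.v, []).append(name)
        if e.kind == "h":
            pair_var[e.pair] = name
    ind_var: dict[int, str] = {}
    for occ in sorted(m.indel_edges):
        ind_var[occ] = mod.add_var(f"xi_{occ}")

    # sibling consistency: head and tail edges of a pair agree
    for pair in sorted(pair_var):
        mod.add_constraint(
            f"sib_{pair[0]}_{pair[1]}",
            {f"x_h_{pair[0]}_{pair[1]}": 1, f"x_t_{pair[0]}_{pair[1]}": -1},
            0,
            0,
        )

    # vertex coverage: one extremity edge XOR the marker's indel edge
    for occ in sorted(m.indel_edges):
        for kind in ("t", "h"):
            v = (occ, kind)
            coeffs = {name: 1.0 for name in ext_at_vertex.get(v, [])}
            coeffs[ind_var[occ]] = 1.0
            mod.add_constraint(f"cover_{occ}{kind}", coeffs, 1, 1)

    # family bounds
    for f in sorted(bounds.bounds):
        lo, hi = bounds.bounds[f]
        in_a, in_b = m.families.families[f]
        coeffs = {
            pair_var[(p, q)]: 1.0 for p in in_a for q in in_b
        }
        if coeffs:
            mod.add_constraint(f"fam_{f}", coeffs, lo, hi)
        elif lo > 0:
            raise ValueError(f"family {f!r} cannot reach lower bound {lo}")

    # --- component labelling ------------------------------------------
    verts = m.vertices()
    y: dict = {}
    z: dict = {}
    l: dict = {}
    for v in verts:
        y[v] = mod.add_var(f"y_{_vname(v)}", 0, ix[v])
        z[v] = mod.add_var(f"z_{_vname(v)}")
        if m.is_cap(v):
            bit = 0 if m.genome_of(v) == "A" else 1
            l[v] = mod.add_var(f"l_{_vname(v)}", bit, bit)
        else:
            l[v] = mod.add_var(f"l_{_vname(v)}")

    # lava pinning of y and l
    for occ in sorted(m.indel_edges):
        g = m.occ_info[occ][0]
        for kind in ("t", "h"):
            v = (occ, kind)
            mod.add_constraint(
                f"ylava_{occ}{kind}", {y[v]: 1, ind_var[occ]: ix[v]}, ub=ix[v]
            )
            if g == "A":
                mod.add_constraint(
                    f"llava_{occ}{kind}", {l[v]: 1, ind_var[occ]: 1}, ub=1
                )
            else:
                mod.add_constraint(
                    f"llava_{occ}{kind}", {l[v]: 1, ind_var[occ]: -1}, lb=0
                )

    # z marks the minimum-id vertex of a lava-free component
    for v in verts:
        mod.add_constraint(f"zmin_{_vname(v)}", {z[v]: ix[v], y[v]: -1}, ub=0)

    # y equal across extremity edges when selected (big-M relaxed)
    for e in m.extremity_edges:
        name = f"x_{e.kind}_{e.pair[0]}_{e.pair[1]}"
        tag = f"{e.kind}_{e.pair[0]}_{e.pair[1]}"
        mod.add_constraint(
            f"yext1_{tag}", {y[e.u]: 1, y[e.v]: -1, name: big_m}, ub=big_m
        )
        mod.add_constraint(
            f"yext2_{tag}", {y[e.v]: 1, y[e.u]: -1, name: big_m}, ub=big_m
        )
        # labels equal across selected extremity edges
        mod.add_constraint(f"lext1_{tag}", {l[e.u]: 1, l[e.v]: -1, name: 1}, ub=1)
        mod.add_constraint(f"lext2_{tag}", {l[e.v]: 1, l[e.u]: -1, name: 1}, ub=1)

    # --- report variables on adjacency edges --------------------------
    r_cycle: dict = {}
    r_path: dict[str, dict] = {"AB": {}, "Aoa": {}, "Ab": {}, "Ba": {}, "Bob": {}}
    r_ab: dict = {}
    adj_edges = []
    for k, e in enumerate(m.adjacency_edges):
        u, v = sorted(e, key=lambda w: ix[w])
        adj_edges.append((k, u, v))
        cap = u if m.is_cap(u) else (v if m.is_cap(v) else None)
        r_ab[k] = mod.add_var(f"r_ab_{k}")
        if cap is None:
            r_cycle[k] = mod.add_var(f"r_C_{k}")
        elif m.genome_of(cap) == "A":
            r_path["AB"][k] = mod.add_var(f"r_AB_{k}")
            r_path["Aoa"][k] = mod.add_var(f"r_Aoa_{k}")
            r_path["Ab"][k] = mod.add_var(f"r_Ab_{k}")
        else:
            r_path["Ba"][k] = mod.add_var(f"r_Ba_{k}")
            r_path["Bob"][k] = mod.add_var(f"r_Bob_{k}")

    for k, u, v in adj_edges:
        # y equal across (always selected) adjacency edges
        mod.add_constraint(f"yadj_{k}", {y[u]: 1, y[v]: -1}, 0, 0)
        # labels equal unless an odd type is reported at this edge
        odd = {r_ab[k]: 1.0}
        for t in ("AB", "Ab", "Ba"):
            if k in r_path[t]:
                odd[r_path[t][k]] = 1.0
        mod.add_constraint(f"ladj1_{k}", {l[u]: 1, l[v]: -1, **{n: -c for n, c in odd.items()}}, ub=0)
        mod.add_constraint(f"ladj2_{k}", {l[v]: 1, l[u]: -1, **{n: -c for n, c in odd.items()}}, ub=0)

        # cycle / A|B reports licensed by z of the lower-id endpoint
        lic = {}
        if k in r_cycle:
            lic[r_cycle[k]] = 1.0
        if k in r_path["AB"]:
            lic[r_path["AB"][k]] = 1.0
        if lic:
            mod.add_constraint(f"zlic_{k}", {**lic, z[u]: -1}, ub=0)

        # odd reports require a label change at the edge
        if k in r_path["AB"]:
            cap, w = (u, v) if m.is_cap(u) else (v, u)
            mod.add_constraint(f"oddAB_{k}", {r_path["AB"][k]: 1, l[w]: -1}, ub=0)
        if k in r_path["Ab"]:
            cap, w = (u, v) if m.is_cap(u) else (v, u)
            mod.add_constraint(f"oddAb_{k}", {r_path["Ab"][k]: 1, l[w]: -1}, ub=0)
        if k in r_path["Ba"]:
            cap, w = (u, v) if m.is_cap(u) else (v, u)
            mod.add_constraint(f"oddBa_{k}", {r_path["Ba"][k]: 1, l[w]: 1}, ub=1)
        mod.add_constraint(f"oddab1_{k}", {r_ab[k]: 1, l[u]: -1, l[v]: -1}, ub=0)
        mod.add_constraint(f"oddab2_{k}", {r_ab[k]: 1, l[u]: 1, l[v]: 1}, ub=2)

        # a|b reports need a neighbouring selected indel edge
        nbr = {}
        for w in (u, v):
            if not m.is_cap(w):
                nbr[ind_var[w[0]]] = 1.0
        mod.add_constraint(f"abind_{k}", {r_ab[k]: 1, **{n: -c for n, c in nbr.items()}}, ub=0)

        # pier reports force the component's y (hence z) to 0
        piers = [r_path[t][k] for t in ("Aoa", "Ab", "Ba", "Bob") if k in r_path[t]]
        if piers:
            for w in (u, v):
                mod.add_constraint(
                    f"piery_{k}_{_vname(w)}",
                    {y[w]: 1, **{p: ix[w] for p in piers}},
                    ub=ix[w],
                )

    # a pseudo-cap in a component with lava vertices must report a pier
    for cap in (*m.caps_a, *m.caps_b):
        k = next(
            kk for kk, u, v in adj_edges if u == cap or v == cap
        )
        piers = [r_path[t][k] for t in ("Aoa", "Ab", "Ba", "Bob") if k in r_path[t]]
        mod.add_constraint(
            f"cappier_{_vname(cap)}", {y[cap]: 1, **{p: 1.0 for p in piers}}, lb=1
        )

    # --- counters, singletons and the objective ------------------------
    n_caps = len(m.caps_a) + len(m.caps_b)
    n_var = mod.add_var("n", 0, len(pair_var))
    mod.add_constraint(
        "def_n", {n_var: 1, **{v: -1.0 for v in pair_var.values()}}, 0, 0
    )
    c_var = mod.add_var("c", 0, len(r_cycle) + 1)
    mod.add_constraint("def_c", {c_var: 1, **{v: -1.0 for v in r_cycle.values()}}, 0, 0)
    counters = {}
    for t, cap_count in (
        ("AB", n_caps), ("Aoa", n_caps), ("Ab", n_caps),
        ("Ba", n_caps), ("Bob", n_caps),
    ):
        counters[t] = mod.add_var(f"p_{t}", 0, max(cap_count, 1))
        mod.add_constraint(
            f"def_p_{t}",
            {counters[t]: 1, **{v: -1.0 for v in r_path[t].values()}},
            0,
            0,
        )
    p_ab = mod.add_var("p_ab", 0, max(len(r_ab), 1))
    mod.add_constraint("def_p_ab", {p_ab: 1, **{v: -1.0 for v in r_ab.values()}}, 0, 0)

    q_var = mod.add_var("q", -max(n_caps, 1), len(r_ab) + 2 * n_caps + 2)
    for alpha in ("Aoa", "Ba"):
        for beta in ("Ab", "Bob"):
            mod.add_constraint(
                f"ceil_{alpha}_{beta}",
                {
                    q_var: 2,
                    p_ab: -1,
                    counters[alpha]: -1,
                    counters[beta]: -1,
                    counters["AB"]: 1,
                },
                lb=0,
            )

    # circular singletons: indicator per circular chromosome
    sing_vars = []
    ci = 0
    for g in (m.genome_a, m.genome_b):
        for chrom in g.chromosomes:
            if not chrom.circular:
                continue
            t_var = mod.add_var(f"t_circ_{ci}")
            ci += 1
            occs = [mk.occurrence_id for mk in chrom.markers]
            mod.add_constraint(
                f"circ_{ci}",
                {t_var: 1, **{ind_var[o]: -1.0 for o in occs}},
                lb=1 - len(occs),
            )
            sing_vars.append(t_var)
    s_var = mod.add_var("s", 0, max(len(sing_vars), 1))
    mod.add_constraint("def_s", {s_var: 1, **{v: -1.0 for v in sing_vars}}, 0, 0)

    mod.objective = {n_var: 1, c_var: -1, q_var: 1, s_var: 1}
    return mod


# ---------------------------------------------------------------------------
# Solving and extraction
# ---------------------------------------------------------------------------

def solve(
    model: IlpModel,
    time_limit: float | None = None,
    solver: str = "highs",
) -> IlpSolution:
    """Solve a model to optimality (or to a time limit) with HiGHS.

    ``solver`` names the backend; only the bundled ``"highs"`` is
    available.  Time-limited runs return the incumbent with its dual
    bound; the gap is ``(objective - bound) / objective``.
    """
    if solver != "highs":
        raise ValueError(f"unknown solver backend {solver!r}; available: 'highs'")
    nv = model.n_vars
    c = np.zeros(nv)
    for v, coef in model.objective.items():
        c[model.var_index[v]] = coef
    rows, cols, vals, clo, chi = [], [], [], [], []
    for i, (_, coeffs, lo, hi) in enumerate(model.constraints):
        for v, coef in coeffs.items():
            rows.append(i)
            cols.append(model.var_index[v])
            vals.append(coef)
        clo.append(lo)
        chi.append(hi)
    a_mat = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(model.constraints), nv)
    )
    options = {"mip_rel_gap": 0.0}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = milp(
        c=c,
        constraints=LinearConstraint(a_mat, np.array(clo), np.array(chi)),
        integrality=np.array([1 if f else 0 for f in model.integer]),
        bounds=Bounds(np.array(model.lb), np.array(model.ub)),
        options=options,
    )
    if res.x is None:
        raise RuntimeError(f"solver returned no incumbent (status {res.status}: {res.message})")
    assignment = dict(zip(model.var_names, res.x))
    objective = round(float(res.fun))
    bound = float(getattr(res, "mip_dual_bound", res.fun))
    status = "optimal" if res.status == 0 else "feasible-with-gap"
    return IlpSolution(status=status, objective=objective, bound=bound, assignment=assignment)


def extract(
    m: MRDGraph, sol: IlpSolution
) -> tuple[ResolvedMatching, ComponentReport, int]:
    """Read the matching off a solution and recompute report and distance.

    Reports in the solution may over-report cost-increasing types, so the
    census and distance are always recomputed from the selected extremity
    edges via the component classifier, never trusted from the solver.
    """
    pairs = set()
    for e in m.extremity_edges:
        if e.kind != "h":
            continue
        val = sol.assignment.get(f"x_h_{e.pair[0]}_{e.pair[1]}", 0.0)
        tail = sol.assignment.get(f"x_t_{e.pair[0]}_{e.pair[1]}", 0.0)
        if abs(val - tail) > 1e-6:
            raise ValueError(f"sibling edges of pair {e.pair} disagree in solution")
        if val > 0.5:
            pairs.add(e.pair)
    match = ResolvedMatching(frozenset(pairs))
    dist, report = resolved_distance(m.genome_a, m.genome_b, match)
    if sol.status == "optimal" and dist != sol.objective:
        raise AssertionError(
            f"recomputed distance {dist} != optimal objective {sol.objective}"
        )
    return match, report, dist


def ilp_distance(
    a: Genome,
    b: Genome,
    model: str = "maximum",
    time_limit: float | None = None,
    solver: str = "highs",
) -> tuple[int, ResolvedMatching, ComponentReport, IlpSolution]:
    """End-to-end: build the MRD and the program, solve, extract."""
    from .genomes import derive_families
    from .mrd import augment, build_mrd

    fams = derive_families(a, b)
    mrd = augment(build_mrd(a, b, fams))
    prog = build_model(mrd, family_bounds(fams, model))
    sol = solve(prog, time_limit=time_limit, solver=solver)
    matching, report, dist = extract(mrd, sol)
    return dist, matching, report, sol
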