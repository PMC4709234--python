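# Port selector grammar

Selectors denote ordered, duplicate-free sets of hierarchical port
identifiers. The grammar, in EBNF (whitespace between tokens is ignored):

```ebnf
selector   = [ union ] ;                      (* empty text = empty set *)
union      = expr , { "," , expr } ;          (* ordered union, dedup    *)
expr       = atom , { ( "+" | ".+" ) , atom } ;
atom       = "(" , union , ")"
           | path ;
path       = component , { component } ;
component  = "/" , ( name | integer | "*" )
           | bracket ;                        (* bracket may omit "/"    *)
bracket    = "[" , item , { "," , item } , "]" ;
item       = name
           | integer
           | integer , ":" , integer ;        (* half-open range i..j-1  *)
name       = letter_or_underscore , { letter | digit | "_" } ;
integer    = digit , { digit } ;
```

Semantics:

* Each `component` contributes one identifier level; a bare `integer`
  after `/` and the bracketed form denote the same integer level, so
  `/med/L1/0` ≡ `/med/L1[0]`.
* A `bracket` with several items is a list of alternatives for that level;
  multi-alternative levels multiply out in **left-major** order
  (`/m/[a,b][0:2]` → `/m/a[0], /m/a[1], /m/b[0], /m/b[1]`).
* `[i:j]` is half-open (`i` inclusive, `j` exclusive): `[0:10]` denotes
  ten indices. Bounds are nonnegative and non-decreasing.
* `a , b` (union) concatenates the two ordered sets, removing duplicates
  and keeping the first occurrence.
* `a + b` (product) concatenates every identifier of `a` with every
  identifier of `b`, left-major.
* `a .+ b` (elementwise join) concatenates the i-th identifier of `a`
  with the i-th of `b`; the operands must have equal cardinality.
* `*` (wildcard) matches any — possibly empty — level suffix. It may
  appear only as the final level, and a wildcard selector cannot be
  expanded or counted standalone: it is resolved against a concrete
  universe of ports (`expand_against`), returning matches in universe
  order.

The canonical rendering emits one fully expanded identifier per union
member in bracket form (`/med/L1[0]`); parsing a rendering reproduces the
original selector's port set and order.

Note the operator overloading split: inside selector *strings*, `+` is the
product above; on Python `Selector` objects, `a + b` is the **union** used
to pool port sets when assembling interfaces. Use `Selector.product()` for
the string-level `+`.
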