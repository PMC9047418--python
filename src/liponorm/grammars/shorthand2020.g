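# Updated (2020) shorthand nomenclature for MS-derived lipid names.
# Whitespace is significant: the single space between the class token
# and the chain specifications is a terminal.  Chain specifications
# nest: an acyl/alkyl branch inside a functional group is itself a full
# chain specification (the context-free pattern).

lipid          = body adduct_clause | body ;
body           = class ' ' chain_list | class ;
class          = [A-Za-z] class_tail ;
class_tail     = [A-Za-z0-9'-] class_tail | '' ;
chain_list     = chain sep chain_list | chain ;
sep            = '/' | '_' ;
chain          = ether_prefix core_chain | core_chain ;
ether_prefix   = 'O-' | 'P-' ;
core_chain     = cd mods ;
cd             = number ':' number db_block | number ':' number ;
db_block       = '(' db_list ')' ;
db_list        = db_item ',' db_list | db_item ;
db_item        = number db_config | number ;
db_config      = 'Z' | 'E' ;
mods           = mod mods | '' ;
mod            = ';' clause ;
clause         = oxy_agg | cycle | fg_list ;
oxy_agg        = 'O' number | 'O' ;
cycle          = '[' number '-' number 'cy' number ':' number mods ']' ;
fg_list        = fg ',' fg_list | fg ;
fg             = acyl_branch | alkyl_branch | pos_fg | counted_fg | plain_fg ;
acyl_branch    = number 'O(' branch_class ' ' core_chain ')'
               | 'O(' branch_class ' ' core_chain ')' ;
branch_class   = 'FA' ;
alkyl_branch   = number '(' core_chain ')' | '(' core_chain ')' ;
pos_fg         = number fg_name stereo_br | number fg_name ;
stereo_br      = '[R]' | '[S]' ;
counted_fg     = '(' fg_name ')' number ;
plain_fg       = fg_name ;
fg_name        = 'COOH' | 'OOH' | 'OMe' | 'OH' | 'oxo' | 'Me' | 'Et'
               | 'Ep' | 'NH2' | 'SH' ;
number         = [0-9] number | [0-9] ;
adduct_clause  = '[M' adduct_token ']' number adduct_sign ;
adduct_token   = adduct_sign adduct_body ;
adduct_body    = [A-Za-z0-9] adduct_body | [A-Za-z0-9] ;
adduct_sign    = '+' | '-' ;
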