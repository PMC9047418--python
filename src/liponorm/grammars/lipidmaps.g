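# LIPID MAPS dialect (the original shorthand style): the class
# token is followed by a parenthesized chain list, sphingoid bases are
# marked with d/t/m hydroxylation prefixes, e.g. PE(16:1(6Z)/16:0),
# Cer(d18:1/16:0), PC(O-16:0/18:1).

lipid        = class '(' chain_list ')' ;
class        = [A-Za-z] class_tail ;
class_tail   = [A-Za-z0-9'-] class_tail | '' ;
chain_list   = chain sep chain_list | chain ;
sep          = '/' | '_' ;
chain        = lcb_prefix cd | ether_prefix cd | cd ;
lcb_prefix   = 'd' | 't' | 'm' ;
ether_prefix = 'O-' | 'P-' ;
cd           = number ':' number db_block | number ':' number ;
db_block     = '(' db_list ')' ;
db_list      = db_item ',' db_list | db_item ;
db_item      = number db_config | number ;
db_config    = 'Z' | 'E' ;
number       = [0-9] number | [0-9] ;
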