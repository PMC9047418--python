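# HMDB dialect: parenthesized chain lists with empty sn slots written
# 0:0, sphingoid d/t prefixes, and both upper- and lowercase ether
# markers, e.g. PC(16:0/0:0), PE(P-16:0e/18:1).

lipid        = class '(' chain_list ')' ;
class        = [A-Za-z] class_tail ;
class_tail   = [A-Za-z0-9'-] class_tail | '' ;
chain_list   = chain sep chain_list | chain ;
sep          = '/' | '_' ;
chain        = lcb_prefix cd | ether_prefix cd ether_suffix | cd ether_suffix | cd ;
lcb_prefix   = 'd' | 't' | 'm' ;
ether_prefix = 'O-' | 'P-' | 'o-' | 'p-' ;
ether_suffix = 'e' ;
cd           = number ':' number db_block | number ':' number ;
db_block     = '(' db_list ')' ;
db_list      = db_item ',' db_list | db_item ;
db_item      = number db_config | number ;
db_config    = 'Z' | 'E' ;
number       = [0-9] number | [0-9] ;
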