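# SwissLipids dialect: parenthesized chain lists like LIPID MAPS, with
# species-level totals also common, e.g. PC(34:1), PE(16:0/18:1),
# and lowercase ether markers seen in some exports.

lipid        = class '(' chain_list ')' ;
class        = [A-Za-z] class_tail ;
class_tail   = [A-Za-z0-9'-] class_tail | '' ;
chain_list   = chain sep chain_list | chain ;
sep          = '/' | '_' ;
chain        = lcb_prefix cd | ether_prefix cd | cd ;
lcb_prefix   = 'd' | 't' | 'm' ;
ether_prefix = 'O-' | 'P-' | 'o-' | 'p-' ;
cd           = number ':' number db_block | number ':' number ;
db_block     = '(' db_list ')' ;
db_list      = db_item ',' db_list | db_item ;
db_item      = number db_config | number ;
db_config    = 'Z' | 'E' ;
number       = [0-9] number | [0-9] ;
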