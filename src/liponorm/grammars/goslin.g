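# Legacy Goslin dialect: space-separated class token, hyphen- (or
# slash-) separated chains, TAG/DAG/MAG class spellings, trailing
# hydroxyl counts after a semicolon and 'a'/'p' ether suffixes,
# e.g. TAG 16:0-18:1-18:1, Cer 18:1;2/16:0, PE 18:0p/22:6.

lipid        = class ' ' chain_list | class ;
class        = [A-Za-z] class_tail ;
class_tail   = [A-Za-z0-9'-] class_tail | '' ;
chain_list   = chain sep chain_list | chain ;
sep          = '-' | '/' | '_' ;
chain        = lcb_prefix core | ether_prefix core | core ether_suffix | core ;
lcb_prefix   = 'd' | 't' | 'm' ;
ether_prefix = 'O-' | 'P-' ;
ether_suffix = 'a' | 'p' ;
core         = cd hydroxyl ;
hydroxyl     = ';' number | '' ;
cd           = number ':' number db_block | number ':' number ;
db_block     = '(' db_list ')' ;
db_list      = db_item ',' db_list | db_item ;
db_item      = number db_config | number ;
db_config    = 'Z' | 'E' ;
number       = [0-9] number | [0-9] ;
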